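"""Final call combination and screening-performance metrics.

The machine screen produces two candidate sets per confidence level — one
from the factor-score scatter matrix, one from the growth-parameter cloud —
which are combined (union by default) into the final prediction.  Against
known labels the prediction is summarized by the screening metrics used for
visual-screening benchmarks:

    accuracy  P  = correctly predicted mutants / actual mutants
    FNR          = undetected mutants          / actual mutants   (= 1 - P)
    FPR          = prediction errors / predicted mutants      ("per predicted")
                 or prediction errors / total plants          ("per plant")

Accuracy here is mutant-detection sensitivity, not overall classification
accuracy: it shares its denominator with the FNR, so P + FNR = 1 always.
Both FPR normalizations are computed because published benchmark tables mix
them: the stated formula divides by predicted mutants, while the printed
per-trial values are reproduced by dividing by total plants (and one trial's
printed value matches neither — `compare_methods` detects and reports such
inconsistencies instead of hiding them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .outlier_screen import CallSet
from .simdata import ScreeningCounts, TABLE1_PRINTED_METRICS

__all__ = [
    "ScreeningMetrics",
    "combine_calls",
    "evaluate",
    "metrics_from_counts",
    "confidence_sweep",
    "compare_methods",
]


@dataclass(frozen=True)
class ScreeningMetrics:
    """Counts plus the four metric ratios for one evaluated call set.

    ``accuracy`` and ``fnr`` are ``nan`` ("not applicable") when the trial
    contains no actual mutants; ``fpr_per_predicted`` is ``nan`` when
    nothing was predicted.
    """

    counts: ScreeningCounts
    accuracy: float
    fnr: float
    fpr_per_predicted: float
    fpr_per_plant: float
    level: float | str = "manual"
    rounding: int = 3

    def rounded(self) -> dict[str, float]:
        r = self.rounding
        return {
            "accuracy": round(self.accuracy, r) if math.isfinite(self.accuracy) else math.nan,
            "fnr": round(self.fnr, r) if math.isfinite(self.fnr) else math.nan,
            "fpr_per_predicted": (round(self.fpr_per_predicted, r)
                                  if math.isfinite(self.fpr_per_predicted) else math.nan),
            "fpr_per_plant": round(self.fpr_per_plant, r),
        }

    def to_row(self) -> dict:
        c = self.counts
        return {
            "level": self.level,
            "total_plants": c.total_plants,
            "actual_mutants": c.actual_mutants,
            "predicted_mutants": c.predicted_mutants,
            "correctly_predicted": c.correctly_predicted,
            "prediction_errors": c.prediction_errors,
            "undetected": c.undetected,
            "accuracy": self.accuracy,
            "fnr": self.fnr,
            "fpr_per_predicted": self.fpr_per_predicted,
            "fpr_per_plant": self.fpr_per_plant,
        }


def combine_calls(scatter: CallSet, growth: CallSet, rule: str = "union") -> CallSet:
    """Merge scatter-matrix and growth-parameter calls into the final set.

    ``rule`` is ``"union"`` (default — either stage suffices, the sensitive
    choice) or ``"intersection"`` (both stages must agree).  Provenance is
    kept in ``parents``; per-stage detail survives in ``per_panel`` keyed by
    stage name.
    """
    if scatter.population != growth.population:
        raise ValueError("call sets cover different populations")
    if rule == "union":
        flagged = scatter.flagged | growth.flagged
    elif rule == "intersection":
        flagged = scatter.flagged & growth.flagged
    else:
        raise ValueError(f"unknown combination rule {rule!r}")
    return CallSet(
        method="combined",
        level=scatter.level,
        flagged=flagged,
        population=scatter.population,
        per_panel={("stage", "scatter"): scatter.flagged,
                   ("stage", "growth"): growth.flagged},
        parents=(scatter.method, growth.method),
        fit_failures=scatter.fit_failures | growth.fit_failures,
    )


def _ratios(c: ScreeningCounts) -> tuple[float, float, float, float]:
    if c.actual_mutants > 0:
        accuracy = c.correctly_predicted / c.actual_mutants
        fnr = c.undetected / c.actual_mutants
    else:
        accuracy = math.nan  # not applicable: no mutants to detect
        fnr = math.nan
    # no predictions means no false positives, so the empty call set scores 0
    fpr_pred = (c.prediction_errors / c.predicted_mutants
                if c.predicted_mutants > 0 else 0.0)
    fpr_plant = c.prediction_errors / c.total_plants
    return accuracy, fnr, fpr_pred, fpr_plant


def metrics_from_counts(counts: ScreeningCounts,
                        level: float | str = "manual") -> ScreeningMetrics:
    """Compute the four metric ratios from raw trial counts."""
    counts.validate()
    accuracy, fnr, fpr_pred, fpr_plant = _ratios(counts)
    return ScreeningMetrics(counts=counts, accuracy=accuracy, fnr=fnr,
                            fpr_per_predicted=fpr_pred, fpr_per_plant=fpr_plant,
                            level=level)


def evaluate(calls: CallSet, truth: pd.DataFrame,
             trial: str = "machine") -> ScreeningMetrics:
    """Score a call set against ground-truth labels.

    Counts are derived set-theoretically: correct = flagged ∩ mutants,
    errors = flagged \\ mutants, undetected = mutants \\ flagged.  A trial
    with zero actual mutants yields ``nan`` accuracy/FNR, never a crash.
    """
    population = set(truth["plant_id"])
    if set(calls.population) != population:
        raise ValueError("call set and truth cover different populations")
    mutants = set(truth.loc[truth["is_mutant"].astype(bool), "plant_id"])
    flagged = set(calls.flagged)
    correct = flagged & mutants
    errors = flagged - mutants
    undetected = mutants - flagged
    counts = ScreeningCounts(
        trial=trial,
        total_plants=len(population),
        actual_mutants=len(mutants),
        predicted_mutants=len(flagged),
        correctly_predicted=len(correct),
        prediction_errors=len(errors),
        undetected=len(undetected),
    )
    return metrics_from_counts(counts, level=calls.level)


def confidence_sweep(
    scatter_calls: dict[float, CallSet],
    growth_calls: dict[float, CallSet],
    truth: pd.DataFrame,
    rule: str = "union",
) -> pd.DataFrame:
    """Evaluate combined calls at every confidence level; rows ordered by level.

    Returns a DataFrame with one ScreeningMetrics row per level plus the
    flagged-set size, suitable for plotting accuracy/FPR/FNR against the
    confidence level.
    """
    levels = sorted(scatter_calls)
    if not levels:
        raise ValueError("no confidence levels supplied")
    if sorted(growth_calls) != levels:
        raise ValueError("scatter and growth call sets cover different levels")
    rows = []
    for level in levels:
        combined = combine_calls(scatter_calls[level], growth_calls[level], rule=rule)
        m = evaluate(combined, truth, trial=f"level_{level:g}")
        row = m.to_row()
        row["n_flagged"] = len(combined.flagged)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_methods(
    machine: pd.DataFrame, manual: list[ScreeningCounts]
) -> dict:
    """Side-by-side comparison of machine screening vs manual trial counts.

    Manual counts are validated, pushed through the same ratio formulas,
    and averaged as the mean of per-trial ratios.  Where printed reference
    ratios exist for a manual trial, each recomputed value is checked
    against the printed one at 3 decimals (both FPR normalizations are
    tried) and any mismatch is reported in ``inconsistencies`` — a printed
    ratio that no normalization reproduces from the trial's own counts is
    surfaced, not silently matched.

    Returns a dict with keys ``manual`` (per-trial + mean rows),
    ``machine`` (the input table as records), ``deltas`` (machine minus
    mean-manual per metric) and ``inconsistencies``.
    """
    for c in manual:
        c.validate()
    manual_metrics = [metrics_from_counts(c, level="manual") for c in manual]
    manual_rows = [m.to_row() | {"trial": m.counts.trial} for m in manual_metrics]
    mean = {
        key: sum(r[key] for r in manual_rows) / len(manual_rows)
        for key in ("accuracy", "fnr", "fpr_per_predicted", "fpr_per_plant")
    }

    inconsistencies = []
    for m in manual_metrics:
        printed = TABLE1_PRINTED_METRICS.get(m.counts.trial)
        if printed is None:
            continue
        r = m.rounded()
        for name, recomputed in (("accuracy", r["accuracy"]), ("fnr", r["fnr"])):
            if abs(recomputed - printed[name]) > 5e-4:
                inconsistencies.append(
                    f"trial {m.counts.trial}: recomputed {name} {recomputed:.3f} "
                    f"!= printed {printed[name]:.3f}")
        fpr_printed = printed["fpr"]
        candidates = {"per_plant": r["fpr_per_plant"],
                      "per_predicted": r["fpr_per_predicted"]}
        if all(abs(v - fpr_printed) > 5e-4 for v in candidates.values()):
            inconsistencies.append(
                f"trial {m.counts.trial}: printed FPR {fpr_printed:.3f} matches "
                f"neither prediction_errors/total_plants "
                f"({candidates['per_plant']:.3f}) nor "
                f"prediction_errors/predicted_mutants "
                f"({candidates['per_predicted']:.3f})")

    machine_rows = machine.to_dict("records") if isinstance(machine, pd.DataFrame) else list(machine)
    deltas = []
    for row in machine_rows:
        deltas.append({
            "level": row.get("level"),
            **{f"d_{k}": row[k] - mean[k] for k in ("accuracy", "fnr", "fpr_per_plant")},
        })
    return {
        "manual": manual_rows,
        "manual_mean": mean,
        "machine": machine_rows,
        "deltas": deltas,
        "inconsistencies": inconsistencies,
    }
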