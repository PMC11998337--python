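"""Synthetic phenotyping populations for mutant-screening studies.

High-throughput plant imaging platforms produce, for every plant on a
multi-well plate, a "phenotypic fingerprint": a vector of several dozen
morphometric and colour traits, plus a projected-rosette-area time series
sampled every other day until flowering.  The imaging hardware and its
trait-extraction software are proprietary, so this module generates
populations with the same statistical structure instead:

* wild-type (WT) plants drawn from a block-correlated Gaussian baseline
  built on a small number of latent morphological factors, so that
  correlation-matrix PCA with the eigenvalue-greater-than-one rule recovers
  the latent factor count on clean data;
* mutant lines, each carrying a line-specific shift of a few traits
  (different plate positions of the same line share the identical effect)
  and a multiplicative perturbation of its growth parameters;
* leaf-area growth series following the logistic growth curve
  ``area(t) = h / (1 + x1 * exp(-x2 * t))`` with multiplicative
  measurement noise.

The printed counts of the reference visual-screening experiment (three
trials of ~102-108 plants containing 8-14 mutants) are packaged here as a
fixture for the evaluation module's worked example.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScreeningConfig",
    "ScreeningCounts",
    "ConfigurationError",
    "generate_population",
    "generate_growth_series",
    "load_table1_fixture",
    "TABLE1_PRINTED_METRICS",
    "write_population",
]


class ConfigurationError(ValueError):
    """Raised when a :class:`ScreeningConfig` violates its invariants."""


def _default_days() -> tuple[int, ...]:
    # every-other-day imaging from transplant to a fixed flowering horizon
    return tuple(range(0, 29, 2))


@dataclass(frozen=True)
class ScreeningConfig:
    """Parameters of one synthetic screening experiment.

    Defaults follow the reference study's scale: ~102 plants on six-well
    plates, 8 of them mutants from 5 distinct lines (a line may occupy
    several wells), 45 static traits, imaging every other day for 28 days.

    Attributes
    ----------
    n_plants : total plants in the trial.
    n_mutant_plants : how many of them are mutants.
    n_mutant_lines : distinct mutant lines; plants of one line share effects.
    n_traits : static trait count (the "fingerprint" width).
    n_latent_factors : latent morphological factors behind the WT baseline.
    trait_effect_size : mutant shift per affected trait, in WT SD units.
    n_affected_traits : traits shifted per mutant line.
    growth_effect : multiplicative factor applied to a mutant's (h, x2).
    noise_cv : coefficient of variation of the area measurement noise.
    days : imaging schedule in days since transplant (strictly increasing).
    seed : master seed; every random draw descends from it.
    plate_layout : wells per plate.
    """

    n_plants: int = 102
    n_mutant_plants: int = 8
    n_mutant_lines: int = 5
    n_traits: int = 45
    n_latent_factors: int = 8
    trait_effect_size: float = 4.0
    n_affected_traits: int = 3
    growth_effect: float = 2.0
    noise_cv: float = 0.02
    days: tuple[int, ...] = field(default_factory=_default_days)
    seed: int = 0
    plate_layout: int = 6

    def __post_init__(self) -> None:
        if min(self.n_plants, self.n_mutant_plants, self.n_mutant_lines,
               self.n_traits, self.n_affected_traits) < 0:
            raise ConfigurationError("all counts must be >= 0")
        if self.n_mutant_plants > self.n_plants:
            raise ConfigurationError(
                f"n_mutant_plants ({self.n_mutant_plants}) exceeds "
                f"n_plants ({self.n_plants})")
        if self.n_mutant_lines > self.n_mutant_plants:
            raise ConfigurationError(
                f"n_mutant_lines ({self.n_mutant_lines}) exceeds "
                f"n_mutant_plants ({self.n_mutant_plants})")
        if self.n_mutant_plants > 0 and self.n_mutant_lines == 0:
            raise ConfigurationError("mutant plants require >= 1 line")
        if len(self.days) == 0:
            raise ConfigurationError("days must be non-empty")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ConfigurationError("days must be strictly increasing")
        if self.n_affected_traits > self.n_traits:
            raise ConfigurationError("n_affected_traits exceeds n_traits")
        if self.plate_layout < 1:
            raise ConfigurationError("plate_layout must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["days"] = list(d["days"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScreeningConfig":
        d = dict(d)
        if "days" in d:
            d["days"] = tuple(d["days"])
        return cls(**d)


# ---------------------------------------------------------------------------
# WT trait baseline
# ---------------------------------------------------------------------------

# Loading strength of each trait on its latent factor; communality 0.9 puts
# the cumulative variance of the retained components above 90% while the
# residual unique variance keeps secondary correlation-matrix eigenvalues
# well below 1, so eigenvalue>1 retention recovers n_latent_factors on
# clean data.
_FACTOR_LOADING = 0.95

# Per-trait location/scale to mimic mixed units (areas in mm^2, lengths in
# mm, unitless indices).  Standardization in the factor model removes them;
# they only make raw CSVs look like real platform output.
_TRAIT_SCALES = (120.0, 8.0, 1.0)
_TRAIT_MEANS = (900.0, 25.0, 0.6)


def _trait_structure(config: ScreeningConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Loading matrix (traits x factors) and per-trait mean/scale."""
    m, q = config.n_traits, config.n_latent_factors
    loadings = np.zeros((m, q))
    for j in range(m):
        loadings[j, j % q] = _FACTOR_LOADING
    scales = np.array([_TRAIT_SCALES[j % 3] for j in range(m)])
    means = np.array([_TRAIT_MEANS[j % 3] for j in range(m)])
    return loadings, means, scales


def _trait_names(m: int) -> list[str]:
    return [f"trait_{j + 1}" for j in range(m)]


def _plant_ids(n: int) -> list[str]:
    return [f"P{idx:04d}" for idx in range(1, n + 1)]


def _assign_lines(config: ScreeningConfig, rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
    """Choose mutant positions and assign them to lines (roughly balanced)."""
    n, nm, nl = config.n_plants, config.n_mutant_plants, config.n_mutant_lines
    mutant_pos = np.sort(rng.choice(n, size=nm, replace=False))
    # round-robin so every line gets >= 1 plant and lines recur at several positions
    line_of_mutant = np.arange(nm) % nl
    rng.shuffle(line_of_mutant)
    line_ids = ["WT"] * n
    for pos, li in zip(mutant_pos, line_of_mutant):
        line_ids[pos] = f"M{li + 1:02d}"
    return mutant_pos, line_ids


def _line_effects(config: ScreeningConfig) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-line trait shift (SD units) and growth multiplier, from a line sub-seed.

    Sub-seeding from (master seed, line index) makes plants of the same line
    exchangeable across positions: the effect depends on the line, never on
    the well it happens to occupy.
    """
    effects: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for li in range(config.n_mutant_lines):
        sub = np.random.default_rng(np.random.SeedSequence([config.seed, 7001, li]))
        traits = sub.choice(config.n_traits, size=config.n_affected_traits, replace=False)
        signs = sub.choice([-1.0, 1.0], size=config.n_affected_traits)
        shift = np.zeros(config.n_traits)
        shift[traits] = signs * config.trait_effect_size
        effects[f"M{li + 1:02d}"] = (shift, np.array([config.growth_effect]))
    return effects


def generate_population(config: ScreeningConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a static phenotype table and its ground-truth labels.

    Returns
    -------
    phenotypes : DataFrame
        Columns ``plant_id, plate, well, line_id, trait_1..trait_m``.
    truth : DataFrame
        Columns ``plant_id, is_mutant, line_id``; one row per plant.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1001]))
    n, m = config.n_plants, config.n_traits
    loadings, means, scales = _trait_structure(config)

    latent = rng.standard_normal((n, config.n_latent_factors))
    unique_sd = np.sqrt(max(1.0 - _FACTOR_LOADING ** 2, 0.0))
    z = latent @ loadings.T + unique_sd * rng.standard_normal((n, m))

    mutant_pos, line_ids = _assign_lines(config, rng)
    effects = _line_effects(config)
    for pos in mutant_pos:
        shift, _ = effects[line_ids[pos]]
        z[pos] += shift  # shift in SD units, applied before unit scaling

    traits = z * scales + means
    ids = _plant_ids(n)
    wells_per_plate = config.plate_layout
    phenotypes = pd.DataFrame(
        {
            "plant_id": ids,
            "plate": [f"PL{idx // wells_per_plate + 1:02d}" for idx in range(n)],
            "well": [f"W{idx % wells_per_plate + 1}" for idx in range(n)],
            "line_id": line_ids,
        }
    )
    phenotypes = pd.concat(
        [phenotypes, pd.DataFrame(traits, columns=_trait_names(m))], axis=1
    )
    is_mutant = np.zeros(n, dtype=bool)
    is_mutant[mutant_pos] = True
    truth = pd.DataFrame({"plant_id": ids, "is_mutant": is_mutant, "line_id": line_ids})
    return phenotypes, truth


# ---------------------------------------------------------------------------
# Growth series
# ---------------------------------------------------------------------------

# WT logistic-growth parameter distributions (rosette projected area, mm^2):
# asymptote ~1200 mm^2 at flowering, initial area h/(1+x1) ~ 15 mm^2,
# half-maximum near day 12.5 (ln(x1)/x2).
_WT_H_MEAN, _WT_H_CV = 1200.0, 0.10
_WT_X1_MEAN, _WT_X1_CV = 80.0, 0.15
_WT_X2_MEAN, _WT_X2_CV = 0.35, 0.08


def logistic_area(t: np.ndarray | float, h: float, x1: float, x2: float) -> np.ndarray | float:
    """Logistic growth curve ``h / (1 + x1 * exp(-x2 * t))``."""
    return h / (1.0 + x1 * np.exp(-x2 * np.asarray(t, dtype=float)))


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    if cv <= 0:
        return np.full(size, mean)
    sigma2 = np.log(1.0 + cv ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def generate_growth_series(
    config: ScreeningConfig, truth: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-plant leaf-area series from the logistic growth model.

    Each plant draws wild-type parameters ``(h, x1, x2)``; mutant plants have
    their line's multiplicative ``growth_effect`` applied to ``(h, x2)``.
    Areas get multiplicative Gaussian noise with CV ``config.noise_cv``,
    truncated at zero.

    Returns
    -------
    series : DataFrame with columns ``plant_id, day, leaf_area``.
    true_params : DataFrame with the generating ``h, x1, x2`` per plant,
        kept for parameter-recovery studies.
    """
    if len(config.days) == 0:  # unreachable via ScreeningConfig, kept for raw dicts
        raise ConfigurationError("days must be non-empty")
    expected = set(_plant_ids(config.n_plants))
    if set(truth["plant_id"]) != expected or len(truth) != config.n_plants:
        raise ConfigurationError("truth table inconsistent with config")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2001]))
    n = config.n_plants
    h = _lognormal(rng, _WT_H_MEAN, _WT_H_CV, n)
    x1 = _lognormal(rng, _WT_X1_MEAN, _WT_X1_CV, n)
    x2 = _lognormal(rng, _WT_X2_MEAN, _WT_X2_CV, n)

    effects = _line_effects(config)
    truth_idx = truth.set_index("plant_id")
    ids = _plant_ids(n)
    for i, pid in enumerate(ids):
        line = truth_idx.loc[pid, "line_id"]
        if truth_idx.loc[pid, "is_mutant"]:
            g = float(effects[line][1][0])
            h[i] *= g
            x2[i] *= g

    days = np.asarray(config.days, dtype=float)
    clean = h[:, None] / (1.0 + x1[:, None] * np.exp(-x2[:, None] * days[None, :]))
    if config.noise_cv > 0:
        noise = 1.0 + config.noise_cv * rng.standard_normal(clean.shape)
        areas = np.maximum(clean * noise, 0.0)
    else:
        areas = clean

    series = pd.DataFrame(
        {
            "plant_id": np.repeat(ids, len(days)),
            "day": np.tile(config.days, n),
            "leaf_area": areas.ravel(),
        }
    )
    true_params = pd.DataFrame({"plant_id": ids, "h": h, "x1": x1, "x2": x2})
    return series, true_params


# ---------------------------------------------------------------------------
# Printed visual-screening counts (worked-example fixture)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreeningCounts:
    """Raw counts of one screening trial (predicted vs actual mutants)."""

    trial: str
    total_plants: int
    actual_mutants: int
    predicted_mutants: int
    correctly_predicted: int
    prediction_errors: int
    undetected: int

    def validate(self) -> None:
        """Check the two count identities; raise ValueError naming violations."""
        problems = []
        if self.correctly_predicted + self.undetected != self.actual_mutants:
            problems.append(
                f"correctly_predicted ({self.correctly_predicted}) + undetected "
                f"({self.undetected}) != actual_mutants ({self.actual_mutants})")
        if self.correctly_predicted + self.prediction_errors != self.predicted_mutants:
            problems.append(
                f"correctly_predicted ({self.correctly_predicted}) + prediction_errors "
                f"({self.prediction_errors}) != predicted_mutants ({self.predicted_mutants})")
        if min(self.total_plants, self.actual_mutants, self.predicted_mutants,
               self.correctly_predicted, self.prediction_errors, self.undetected) < 0:
            problems.append("negative count")
        if problems:
            raise ValueError(f"invalid counts for trial {self.trial}: " + "; ".join(problems))


#: Published per-trial ratios of the three visual-screening trials, as printed
#: (3 decimals).  Note the trial-3 FPR is inconsistent with its own counts;
#: ``evaluation.compare_methods`` detects and reports that.
TABLE1_PRINTED_METRICS = {
    "1": {"accuracy": 0.875, "fpr": 0.069, "fnr": 0.125},
    "2": {"accuracy": 0.429, "fpr": 0.046, "fnr": 0.571},
    "3": {"accuracy": 0.625, "fpr": 0.058, "fnr": 0.375},
    "mean": {"accuracy": 0.643, "fpr": 0.058, "fnr": 0.357},
}


def load_table1_fixture() -> list[ScreeningCounts]:
    """The three visual-screening trials' printed counts.

    Order of the packed tuples: (total plants, actual mutants, predicted
    mutants, correctly predicted, prediction errors, undetected).
    """
    raw = [
        ("1", 102, 8, 14, 7, 7, 1),
        ("2", 108, 14, 11, 6, 5, 8),
        ("3", 102, 8, 13, 5, 8, 3),
    ]
    counts = [ScreeningCounts(*row) for row in raw]
    for c in counts:
        c.validate()
    return counts


# ---------------------------------------------------------------------------
# CSV / config I/O
# ---------------------------------------------------------------------------


def write_population(
    outdir: str | Path,
    config: ScreeningConfig,
    phenotypes: pd.DataFrame,
    truth: pd.DataFrame,
    series: pd.DataFrame,
) -> dict[str, Path]:
    """Write the standard CSV triplet plus the config as JSON; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": outdir / "phenotypes.csv",
        "growth": outdir / "growth.csv",
        "truth": outdir / "truth.csv",
        "config": outdir / "config.json",
    }
    phenotypes.to_csv(paths["phenotypes"], index=False)
    series.to_csv(paths["growth"], index=False)
    truth.to_csv(paths["truth"], index=False)
    paths["config"].write_text(json.dumps(config.to_dict(), indent=2))
    return paths
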