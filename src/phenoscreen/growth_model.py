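"""Logistic growth-curve (LGC) fitting and growth-parameter screening.

Rosette projected area over time follows a logistic growth curve

    area(t) = h / (1 + x1 * exp(-x2 * t))

with ``h`` the asymptotic (maximum) leaf area in mm^2, ``x2`` the intrinsic
growth rate per day, and ``x1`` a unitless shape/offset parameter (the
initial area is ``h / (1 + x1)``; half-maximum is reached at
``t = ln(x1) / x2``).  Each plant's series is fitted by bounded nonlinear
least squares; on top of the fit, two correction offsets are read off as
model-minus-observed residuals at two anchor times — ``k`` at the
mid-series anchor ``p1`` and ``s`` at the final observation ``p2``.  They
quantify how far the observed trajectory sits from its own logistic at the
two checkpoints.

A plant has a single growth trajectory, so one logistic is fitted to the
full series and both anchors are evaluated on it; an alternative two-window
interpretation (separate fits up to ``p1`` and up to ``p2``, yielding two
asymptotes ``h`` and ``H``) is available behind the ``two_window`` flag and
compared in the methods documentation.

Mutant screening reuses the pairwise confidence-ellipse procedure on the
standardized fitted-parameter cloud ``(h, k, s, x1, x2)``: a plant whose
growth dynamics deviate from the population shows up as an outlier in at
least one parameter pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .outlier_screen import CallSet, screen_scatter_matrix

__all__ = [
    "LGCFit",
    "IneligibleSeriesError",
    "InsufficientDataError",
    "fit_lgc",
    "fit_population",
    "lgc_predict",
    "screen_growth_params",
]

GROWTH_PARAM_COLUMNS = ("h", "k", "s", "x1", "x2")


class IneligibleSeriesError(ValueError):
    """Series too short or entirely zero — not fittable."""


class InsufficientDataError(ValueError):
    """Too few converged fits to screen the parameter cloud."""


@dataclass(frozen=True)
class LGCFit:
    """Fitted logistic growth parameters and diagnostics for one plant.

    ``k`` and ``s`` are the correction offsets (model minus observed area,
    mm^2) at the anchor times ``p1`` (mid-series) and ``p2`` (last
    observation).  ``h_window`` is only populated under the two-window
    interpretation, as the early-window asymptote.
    """

    plant_id: str
    h: float
    x1: float
    x2: float
    k: float
    s: float
    p1: float
    p2: float
    rss: float
    converged: bool
    n_points: int
    degenerate: bool = False
    h_window: float | None = None


def _logistic(t: np.ndarray, h: float, x1: float, x2: float) -> np.ndarray:
    return h / (1.0 + x1 * np.exp(-x2 * t))


def lgc_predict(fit: LGCFit, t) -> np.ndarray | float:
    """Evaluate the fitted logistic at time(s) ``t`` (days).

    Monotone increasing in ``t`` and approaching ``h`` as ``t`` grows.
    Raises on an unconverged fit.
    """
    if not fit.converged:
        raise ValueError(f"fit for {fit.plant_id} did not converge")
    return _logistic(np.asarray(t, dtype=float), fit.h, fit.x1, fit.x2)


def _initial_guesses(t: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                     n_starts: int) -> list[np.ndarray]:
    """Heuristic start plus jittered multi-starts.

    h0 = max area; x2_0 from the log-slope of the rising phase; x1_0 from
    the first observation via area(t0) = h / (1 + x1 exp(-x2 t0)).
    """
    h0 = float(np.max(y)) * 1.05
    pos = y > 0
    x2_0 = 0.3
    if pos.sum() >= 2:
        # slope of log(y) in early (below half-max) growth approximates x2
        early = pos & (y < 0.5 * np.max(y))
        tt, yy = (t[early], y[early]) if early.sum() >= 2 else (t[pos], y[pos])
        slope = np.polyfit(tt, np.log(yy), 1)[0]
        if np.isfinite(slope) and slope > 1e-4:
            x2_0 = float(min(slope, 5.0))
    y0 = y[0] if y[0] > 0 else max(np.min(y[pos]), 1e-6)
    x1_0 = max((h0 / y0 - 1.0) * np.exp(x2_0 * t[0]), 1e-3)
    base = np.array([h0, x1_0, x2_0])
    guesses = [base]
    for _ in range(n_starts - 1):
        jitter = np.exp(rng.normal(0.0, 0.4, size=3))
        guesses.append(base * jitter)
    return guesses


def fit_lgc(
    series: pd.DataFrame,
    plant_id: str | None = None,
    n_starts: int = 5,
    two_window: bool = False,
    seed: int = 0,
) -> LGCFit:
    """Fit the logistic growth curve to one plant's (day, leaf_area) series.

    Bounded least squares (h in (0, 10*max area], x1 in (1e-6, 1e6],
    x2 in (1e-4, 5]) with multi-start initialization: one heuristic start
    plus jittered restarts from a fixed RNG stream, keeping the lowest
    residual sum of squares.  Ill-conditioned data yield
    ``converged=False`` with diagnostics rather than an exception.

    Raises
    ------
    IneligibleSeriesError
        Fewer than 4 time points, or all areas zero.
    """
    if plant_id is None:
        plant_id = str(series["plant_id"].iloc[0]) if "plant_id" in series else "?"
    t = np.asarray(series["day"], dtype=float)
    y = np.asarray(series["leaf_area"], dtype=float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    if len(t) < 4:
        raise IneligibleSeriesError(
            f"plant {plant_id}: {len(t)} points (< 4) — ineligible for fitting")
    if np.all(y <= 0):
        raise IneligibleSeriesError(f"plant {plant_id}: all-zero area series")

    p1 = float(np.median(t))
    p2 = float(t[-1])
    n_points = len(t)

    if np.ptp(y) == 0:  # strictly constant positive series: no growth signal
        return LGCFit(plant_id=plant_id, h=float(y[0]), x1=np.nan, x2=np.nan,
                      k=np.nan, s=np.nan, p1=p1, p2=p2, rss=np.nan,
                      converged=False, n_points=n_points, degenerate=True)

    lo = np.array([np.finfo(float).tiny, 1e-6, 1e-4])
    hi = np.array([10.0 * np.max(y), 1e6, 5.0])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3001]))

    def residuals(params, tt=t, yy=y):
        return _logistic(tt, *params) - yy

    best = None
    for guess in _initial_guesses(t, y, rng, n_starts):
        guess = np.clip(guess, lo * (1 + 1e-12), hi)
        try:
            sol = least_squares(residuals, guess, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        return LGCFit(plant_id=plant_id, h=np.nan, x1=np.nan, x2=np.nan,
                      k=np.nan, s=np.nan, p1=p1, p2=p2, rss=np.nan,
                      converged=False, n_points=n_points)

    h, x1, x2 = (float(v) for v in best.x)
    rss = float(2.0 * best.cost)

    y_p1 = float(np.interp(p1, t, y))
    y_p2 = float(y[-1])
    k = float(_logistic(np.array([p1]), h, x1, x2)[0] - y_p1)
    s = float(_logistic(np.array([p2]), h, x1, x2)[0] - y_p2)

    h_window = None
    if two_window:
        early = t <= p1
        if early.sum() >= 4 and np.ptp(y[early]) > 0:
            sub = pd.DataFrame({"day": t[early], "leaf_area": y[early]})
            wfit = fit_lgc(sub, plant_id=plant_id, n_starts=n_starts,
                           two_window=False, seed=seed)
            if wfit.converged:
                h_window = wfit.h

    return LGCFit(plant_id=plant_id, h=h, x1=x1, x2=x2, k=k, s=s,
                  p1=p1, p2=p2, rss=rss, converged=True,
                  n_points=n_points, h_window=h_window)


def fit_population(
    series: pd.DataFrame, n_starts: int = 5, seed: int = 0, two_window: bool = False
) -> pd.DataFrame:
    """Fit every plant in a long-format growth table.

    Plants with fewer than 4 points or all-zero series are recorded with
    ``converged=False`` and an ``ineligible`` flag instead of raising, so a
    single bad well never aborts a screening run.

    Returns a DataFrame with one row per plant: the LGCFit fields plus
    ``ineligible``.
    """
    rows = []
    for pid, grp in series.groupby("plant_id", sort=True):
        try:
            fit = fit_lgc(grp, plant_id=str(pid), n_starts=n_starts,
                          seed=seed, two_window=two_window)
            rows.append({**fit.__dict__, "ineligible": False})
        except IneligibleSeriesError:
            rows.append({
                "plant_id": str(pid), "h": np.nan, "x1": np.nan, "x2": np.nan,
                "k": np.nan, "s": np.nan, "p1": np.nan, "p2": np.nan,
                "rss": np.nan, "converged": False, "n_points": len(grp),
                "degenerate": False, "h_window": None, "ineligible": True,
            })
    return pd.DataFrame(rows)


def screen_growth_params(
    fits: pd.DataFrame,
    levels: Iterable[float],
    min_panels: int = 1,
    robust: bool = False,
) -> dict[float, CallSet]:
    """Pairwise-ellipse screening on the fitted (h, k, s, x1, x2) cloud.

    Converged fits are standardized column-wise and passed through the
    scatter-matrix ellipse procedure; unconverged or ineligible plants are
    carried in each CallSet's ``fit_failures`` — candidate anomalies in
    their own right, reported separately rather than silently merged.

    Raises
    ------
    InsufficientDataError
        Fewer than 10 converged fits.
    """
    converged = fits[fits["converged"].astype(bool)]
    failures = frozenset(fits.loc[~fits["converged"].astype(bool), "plant_id"])
    if len(converged) < 10:
        raise InsufficientDataError(
            f"only {len(converged)} converged fits (< 10) — cannot screen")
    params = converged.set_index("plant_id")[list(GROWTH_PARAM_COLUMNS)].astype(float)
    sd = params.std(ddof=1)
    constant = list(sd.index[sd == 0])
    if constant:
        # zero-spread parameters (e.g. k = s = 0 on noiseless data) carry no
        # screening signal; drop them like standardize drops constant traits
        import warnings

        warnings.warn(
            f"dropping constant growth parameter(s) {constant} from the screen",
            UserWarning, stacklevel=2)
        params = params.drop(columns=constant)
        sd = sd.drop(index=constant)
    if params.shape[1] < 2:
        from .outlier_screen import DegenerateGeometryError

        raise DegenerateGeometryError(
            "growth-parameter cloud is degenerate: fewer than 2 parameters "
            f"vary across plants (constant: {constant})")
    z = (params - params.mean()) / sd
    raw = screen_scatter_matrix(z, levels, min_panels=min_panels, robust=robust)
    population = frozenset(fits["plant_id"])
    out = {}
    for level, cs in raw.items():
        out[level] = CallSet(
            method="growth",
            level=level,
            flagged=cs.flagged,
            population=population,
            per_panel=cs.per_panel,
            fit_failures=failures,
        )
    return out
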