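"""Confidence-ellipse outlier calling on pairwise scatter panels.

A plant is a mutant candidate if it falls outside the confidence ellipse in
at least one panel of the pairwise scatter matrix of its screening
variables (factor scores, or fitted growth parameters).  The ellipse for a
panel is the classical Mahalanobis ellipse: with sample mean ``mu`` and
sample covariance ``S`` of the panel's two columns, a point ``p`` is inside
at confidence ``level`` iff

    (p - mu)' S^{-1} (p - mu)  <=  chi2.ppf(level, df=2)

which under a bivariate normal model contains probability mass ``level``.
Because the overall flag is a union over k*(k-1)/2 panels, the per-plant
null flag rate is substantially above ``1 - level`` — the screen is
deliberately sensitive, trading false positives for few misses.

An optional robust covariance (minimum covariance determinant) can replace
the classical estimate for heavily contaminated populations; the default
remains the classical fit on the full sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_LEVELS",
    "METHODS_LEVELS",
    "EllipseModel",
    "CallSet",
    "DegenerateGeometryError",
    "fit_pair_ellipse",
    "screen_scatter_matrix",
    "plot_scatter_matrix",
]

#: Default confidence-level sweep used in the screening experiments.
DEFAULT_LEVELS: tuple[float, ...] = (0.75, 0.80, 0.85, 0.90, 0.95, 0.99, 0.999)
#: Alternate preset covering the narrower high-confidence sweep.
METHODS_LEVELS: tuple[float, ...] = (0.95, 0.97, 0.99, 0.995, 0.999)


class DegenerateGeometryError(ValueError):
    """Covariance of a scatter panel is singular (collinear points)."""


@dataclass(frozen=True)
class EllipseModel:
    """A fitted confidence ellipse for one scatter panel."""

    pair: tuple[str, str]
    center: np.ndarray
    covariance: np.ndarray
    level: float
    threshold: float  # chi-square(2 df) quantile at `level`

    def mahalanobis_sq(self, points: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distances of points (n x 2) from the center."""
        d = np.atleast_2d(points) - self.center
        solved = np.linalg.solve(self.covariance, d.T)
        return np.einsum("ij,ji->i", d, solved)

    def is_outside(self, points: np.ndarray) -> np.ndarray:
        return self.mahalanobis_sq(points) > self.threshold


@dataclass
class CallSet:
    """A set of mutant-candidate calls from one screening stage.

    ``method`` is one of ``scatter``, ``growth``, ``combined``, ``manual``.
    ``per_panel`` maps a panel (pair of variable names) to the ids flagged in
    that panel; ``parents`` records which stages a combined set merged; and
    ``fit_failures`` carries plants that could not be screened (e.g. growth
    fits that did not converge) — reported separately, never silently merged
    into ``flagged``.
    """

    method: str
    level: float | str
    flagged: frozenset
    population: frozenset
    per_panel: dict[tuple[str, str], frozenset] = field(default_factory=dict)
    parents: tuple[str, ...] = ()
    fit_failures: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.flagged = frozenset(self.flagged)
        self.population = frozenset(self.population)
        self.fit_failures = frozenset(self.fit_failures)
        if not self.flagged <= self.population:
            raise ValueError("flagged ids not contained in population")

    def to_jsonable(self) -> dict:
        return {
            "method": self.method,
            "level": self.level,
            "flagged": sorted(self.flagged),
            "population_size": len(self.population),
            "per_panel": {
                f"{a}|{b}": sorted(ids) for (a, b), ids in self.per_panel.items()
            },
            "parents": list(self.parents),
            "fit_failures": sorted(self.fit_failures),
        }


def fit_pair_ellipse(
    points: np.ndarray,
    level: float,
    pair: tuple[str, str] = ("x", "y"),
    robust: bool = False,
) -> EllipseModel:
    """Fit a confidence ellipse to an (n x 2) point cloud.

    Classical mean/covariance by default; ``robust=True`` substitutes the
    minimum covariance determinant estimate.

    Raises
    ------
    DegenerateGeometryError
        If the panel's covariance is singular (all points collinear).
    ValueError
        If n < 3 or level outside (0, 1).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if pts.shape[0] < 3:
        raise ValueError(f"need >= 3 points to fit an ellipse, got {pts.shape[0]}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if robust:
        from sklearn.covariance import MinCovDet

        mcd = MinCovDet(random_state=0).fit(pts)
        center, cov = mcd.location_, mcd.covariance_
    else:
        center = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False, ddof=1)
    det = np.linalg.det(cov)
    if not np.isfinite(det) or det <= np.finfo(float).tiny:
        raise DegenerateGeometryError(
            f"singular covariance for panel {pair[0]} vs {pair[1]} "
            "(collinear or constant points)")
    threshold = float(stats.chi2.ppf(level, df=2))
    return EllipseModel(pair=tuple(pair), center=center, covariance=cov,
                        level=level, threshold=threshold)


def _screen_single_axis(values: pd.Series, level: float) -> frozenset:
    """k = 1 fallback: two-sided normal-quantile interval on the lone axis."""
    mu, sd = values.mean(), values.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateGeometryError("zero variance on the single screening axis")
    half_width = stats.norm.ppf(0.5 + level / 2.0) * sd
    outside = (values - mu).abs() > half_width
    return frozenset(values.index[outside])


def screen_scatter_matrix(
    scores: pd.DataFrame,
    levels: Iterable[float] = DEFAULT_LEVELS,
    min_panels: int = 1,
    robust: bool = False,
) -> dict[float, CallSet]:
    """Flag plants outside confidence ellipses across all pairwise panels.

    For each unordered pair of columns an ellipse is fitted at each
    confidence level; a plant is flagged overall if it lies outside in at
    least ``min_panels`` panels (default 1).  With a single column the
    two-sided normal interval replaces the ellipse.

    Parameters
    ----------
    scores : DataFrame indexed by plant_id; columns are screening variables
        (factor scores FAC_1.. or growth parameters).
    levels : confidence levels, each in (0, 1).
    min_panels : panels a plant must violate to be flagged.
    robust : use the robust (MCD) covariance per panel.

    Returns
    -------
    dict mapping level -> CallSet (with per-panel detail).
    """
    if isinstance(scores, pd.DataFrame) and scores.index.duplicated().any():
        raise ValueError("duplicate ids in scores index")
    levels = sorted(set(float(lv) for lv in levels))
    if not levels:
        raise ValueError("levels must be non-empty")
    population = frozenset(scores.index)
    cols = list(scores.columns)
    out: dict[float, CallSet] = {}
    for level in levels:
        if len(cols) == 1:
            flagged = _screen_single_axis(scores[cols[0]], level)
            per_panel = {(cols[0], cols[0]): flagged}
            counts = pd.Series({pid: 1 for pid in flagged}, dtype=int)
        else:
            per_panel = {}
            counts = pd.Series(0, index=scores.index, dtype=int)
            for a, b in combinations(cols, 2):
                pts = scores[[a, b]].to_numpy(dtype=float)
                ellipse = fit_pair_ellipse(pts, level, pair=(a, b), robust=robust)
                outside = ellipse.is_outside(pts)
                ids = frozenset(scores.index[outside])
                per_panel[(a, b)] = ids
                counts[outside] += 1
            flagged = frozenset(counts.index[counts >= min_panels])
        out[level] = CallSet(
            method="scatter",
            level=level,
            flagged=flagged,
            population=population,
            per_panel=per_panel,
        )
    return out


def plot_scatter_matrix(
    scores: pd.DataFrame,
    level: float = 0.95,
    callset: CallSet | None = None,
    path: str | None = None,
):
    """Render the pairwise scatter matrix with confidence ellipses (PNG).

    Flagged plants (from ``callset`` if given, else recomputed at ``level``)
    are drawn in red.  Returns the matplotlib Figure; saves to ``path`` if
    provided.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if callset is None:
        callset = screen_scatter_matrix(scores, [level])[level]
    cols = list(scores.columns)
    k = len(cols)
    fig, axes = plt.subplots(k, k, figsize=(2.0 * k, 2.0 * k), squeeze=False)
    theta = np.linspace(0, 2 * np.pi, 200)
    circle = np.stack([np.cos(theta), np.sin(theta)])
    flagged_mask = scores.index.isin(list(callset.flagged))
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            ax = axes[i][j]
            if i == j:
                ax.hist(scores[a], bins=20, color="grey")
            else:
                ellipse = fit_pair_ellipse(
                    scores[[b, a]].to_numpy(dtype=float), level, pair=(b, a))
                L = np.linalg.cholesky(ellipse.covariance)
                ring = (ellipse.center[:, None]
                        + np.sqrt(ellipse.threshold) * (L @ circle))
                ax.plot(ring[0], ring[1], "r--", lw=0.8)
                ax.scatter(scores[b][~flagged_mask], scores[a][~flagged_mask],
                           s=4, c="k")
                ax.scatter(scores[b][flagged_mask], scores[a][flagged_mask],
                           s=8, c="r")
            ax.set_xticks([])
            ax.set_yticks([])
            if i == k - 1:
                ax.set_xlabel(b, fontsize=7)
            if j == 0:
                ax.set_ylabel(a, fontsize=7)
    fig.suptitle(f"confidence level {level:g}")
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
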