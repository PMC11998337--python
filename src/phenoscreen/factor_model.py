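"""Factor extraction from the phenotype matrix.

The screening variables are factor scores: each plant's coordinates on the
principal components of the standardized (correlation-scale) trait matrix,
with components retained by the eigenvalue-greater-than-one rule.  Scores
are scaled to unit variance per component so that every retained axis
enters the downstream confidence-ellipse screen on an equal footing.

Traits mix units (areas in mm^2, lengths in mm, unitless shape and colour
indices), which is why the PCA is run on the correlation matrix, i.e. after
z-scoring each trait.  No rotation is applied by default; a varimax option
exists for users who prefer rotated factors.

Ward/Euclidean hierarchical clustering of the standardized matrix provides
the complementary dendrogram-plus-heatmap view of the population.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

logger = logging.getLogger(__name__)

__all__ = [
    "FactorScores",
    "standardize",
    "compute_factors",
    "cluster_phenotypes",
]

_METADATA_COLUMNS = ("plant_id", "plate", "well", "line_id")


def _trait_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Numeric trait columns of a phenotype table, indexed by plant_id."""
    if "plant_id" in table.columns:
        if table["plant_id"].duplicated().any():
            dupes = table.loc[table["plant_id"].duplicated(), "plant_id"].tolist()
            raise ValueError(f"duplicate plant_id values: {dupes}")
        table = table.set_index("plant_id")
    traits = table.drop(columns=[c for c in _METADATA_COLUMNS if c in table.columns])
    traits = traits.select_dtypes(include=[np.number])
    return traits


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each trait column (sample SD, n-1 denominator).

    Zero-variance columns carry no screening information on the correlation
    scale; they are dropped with a warning and listed in the result's
    ``attrs["dropped_columns"]``.

    Raises
    ------
    ValueError
        If fewer than 3 plants, or fewer than 2 non-constant trait columns
        survive.
    """
    traits = _trait_matrix(table)
    if traits.isna().any().any():
        raise ValueError("phenotype table contains missing trait values")
    if len(traits) < 3:
        raise ValueError(f"need >= 3 plants, got {len(traits)}")
    sd = traits.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(
            f"dropping {len(constant)} zero-variance trait column(s): {constant}",
            UserWarning,
            stacklevel=2,
        )
        logger.warning("dropped zero-variance columns: %s", constant)
        traits = traits.drop(columns=constant)
        sd = sd.drop(index=constant)
    if traits.shape[1] < 2:
        raise ValueError(
            f"need >= 2 non-constant trait columns, got {traits.shape[1]}")
    z = (traits - traits.mean(axis=0)) / sd
    z.attrs["dropped_columns"] = constant
    return z


@dataclass
class FactorScores:
    """Retained principal-component scores with their decomposition metadata.

    Attributes
    ----------
    scores : DataFrame (plants x retained components), columns FAC_1..FAC_k,
        each scaled to unit sample variance.
    eigenvalues : all eigenvalues of the trait correlation matrix,
        non-increasing; the first ``n_retained`` exceed the threshold.
    loadings : DataFrame (traits x retained components); loading = trait-score
        correlation = eigenvector * sqrt(eigenvalue).
    variance_explained : cumulative proportion of total variance carried by
        the retained components.
    retention_threshold : the eigenvalue cutoff used.
    """

    scores: pd.DataFrame
    eigenvalues: np.ndarray
    loadings: pd.DataFrame
    variance_explained: np.ndarray
    retention_threshold: float = 1.0
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.scores.shape[1]

    def factor_names(self) -> list[str]:
        return list(self.scores.columns)


def _varimax(loadings: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Orthogonal varimax rotation matrix for a loading matrix."""
    m, k = loadings.shape
    R = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        L = loadings @ R
        u, s, vt = np.linalg.svd(
            loadings.T @ (L ** 3 - L @ np.diag(np.sum(L ** 2, axis=0)) / m))
        R = u @ vt
        new_var = np.sum(s)
        if new_var <= var * (1 + tol):
            break
        var = new_var
    return R


def compute_factors(
    z: pd.DataFrame, retention_threshold: float = 1.0, rotate: str | None = None
) -> FactorScores:
    """PCA of the standardized trait matrix with eigenvalue-based retention.

    Eigendecomposition of the sample correlation matrix; components whose
    eigenvalue exceeds ``retention_threshold`` (default 1.0, the
    Kaiser/Guttman rule) are retained.  At least one component is always
    kept.  Scores are projections rescaled to unit sample variance.  The
    sign of each component is fixed so its largest-magnitude loading is
    positive, making results reproducible across platforms.

    ``rotate="varimax"`` applies an orthogonal varimax rotation to the
    retained loadings (and rotates the scores to match); the default is no
    rotation.
    """
    if rotate not in (None, "varimax"):
        raise ValueError(f"unknown rotation {rotate!r}")
    X = np.asarray(z, dtype=float)
    if np.isnan(X).any():
        raise ValueError("standardized matrix contains NaNs")
    n, m = X.shape
    corr = (X.T @ X) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    eigvals = np.clip(eigvals, 0.0, None)

    k = int(np.sum(eigvals > retention_threshold))
    k = max(k, 1)
    V = eigvecs[:, :k]
    lam = eigvals[:k]

    # deterministic sign: largest-|loading| entry of each eigenvector positive
    flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    V = V * flip

    with np.errstate(divide="ignore", invalid="ignore"):
        scores = X @ V / np.sqrt(lam)
    load_mat = V * np.sqrt(lam)
    if rotate == "varimax" and k > 1:
        R = _varimax(load_mat)
        load_mat = load_mat @ R
        scores = scores @ R
    names = [f"FAC_{i + 1}" for i in range(k)]
    scores_df = pd.DataFrame(scores, index=z.index, columns=names)
    loadings = pd.DataFrame(load_mat, index=z.columns, columns=names)
    cum = np.cumsum(eigvals)[:k] / m
    return FactorScores(
        scores=scores_df,
        eigenvalues=eigvals,
        loadings=loadings,
        variance_explained=cum,
        retention_threshold=retention_threshold,
        dropped_columns=list(z.attrs.get("dropped_columns", [])),
    )


def cluster_phenotypes(z: pd.DataFrame, n_clusters: int = 2) -> tuple[np.ndarray, pd.Series]:
    """Ward-linkage hierarchical clustering on Euclidean distances.

    Returns the scipy linkage matrix (for dendrogram/heatmap rendering) and
    flat cluster labels at the requested cluster count.

    Raises
    ------
    ValueError
        On duplicate plant ids or fewer than 2 plants.
    """
    if z.index.duplicated().any():
        raise ValueError("duplicate plant_ids in standardized matrix")
    if len(z) < 2:
        raise ValueError("need >= 2 plants to cluster")
    linkage = sch.linkage(np.asarray(z, dtype=float), method="ward")
    labels = sch.fcluster(linkage, t=n_clusters, criterion="maxclust")
    return linkage, pd.Series(labels, index=z.index, name="cluster")
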