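"""Standardization, correlation-PCA retention, and Ward clustering."""

import numpy as np
import pandas as pd
import pytest

from phenoscreen import cluster_phenotypes, compute_factors, standardize


def _frame(arr, prefix="t"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
                        index=[f"P{i}" for i in range(arr.shape[0])])


class TestStandardize:
    def test_hand_computed_z_scores(self):
        z = standardize(_frame([[1, 10], [2, 20], [3, 30]]))
        np.testing.assert_allclose(z["t0"], [-1.0, 0.0, 1.0])

    def test_constant_column_dropped_with_warning(self):
        df = _frame([[1, 5, 2], [2, 5, 4], [3, 5, 9]])
        with pytest.warns(UserWarning, match="zero-variance"):
            z = standardize(df)
        assert list(z.columns) == ["t0", "t2"]
        assert z.attrs["dropped_columns"] == ["t1"]

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        z1 = standardize(_frame(rng.normal(size=(20, 4))))
        z2 = standardize(z1)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)

    def test_too_few_nonconstant_columns_rejected(self):
        df = _frame([[1, 5], [2, 5], [3, 5]])
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            standardize(df)

    def test_too_few_plants_rejected(self):
        with pytest.raises(ValueError, match=">= 3 plants"):
            standardize(_frame([[1, 2], [3, 4]]))

    def test_missing_values_rejected(self):
        df = _frame([[1, 2], [np.nan, 4], [5, 6]])
        with pytest.raises(ValueError, match="missing"):
            standardize(df)


class TestComputeFactors:
    def test_two_trait_eigenvalues_are_one_plus_minus_r(self):
        rng = np.random.default_rng(1)
        shared = rng.normal(size=300)
        x = shared + 0.8 * rng.normal(size=300)
        y = shared + 0.8 * rng.normal(size=300)
        z = standardize(_frame(np.column_stack([x, y])))
        r = abs(np.corrcoef(z["t0"], z["t1"])[0, 1])
        f = compute_factors(z)
        np.testing.assert_allclose(sorted(f.eigenvalues, reverse=True),
                                   [1 + r, 1 - r], atol=1e-10)
        assert f.n_retained == 1

    def test_latent_factor_count_recovered_on_clean_baseline(self):
        from phenoscreen import ScreeningConfig, generate_population

        cfg = ScreeningConfig(seed=4, n_mutant_plants=0, n_mutant_lines=0)
        phenotypes, _ = generate_population(cfg)
        f = compute_factors(standardize(phenotypes))
        assert f.n_retained == 8

    def test_retained_scores_uncorrelated_unit_variance(self, default_population):
        _, phenotypes, _ = default_population
        f = compute_factors(standardize(phenotypes))
        corr = np.corrcoef(f.scores.to_numpy(), rowvar=False)
        off = corr - np.diag(np.diag(corr))
        assert np.abs(off).max() < 1e-10
        np.testing.assert_allclose(f.scores.var(ddof=1), 1.0, atol=1e-10)

    def test_eigenvalue_sum_equals_trait_count(self, default_population):
        _, phenotypes, _ = default_population
        z = standardize(phenotypes)
        f = compute_factors(z)
        assert f.eigenvalues.sum() == pytest.approx(z.shape[1], abs=1e-8)

    def test_scores_invariant_to_column_order(self, default_population):
        _, phenotypes, _ = default_population
        z = standardize(phenotypes)
        f1 = compute_factors(z)
        shuffled = z[list(z.columns[::-1])]
        shuffled.attrs["dropped_columns"] = []
        f2 = compute_factors(shuffled)
        np.testing.assert_allclose(f1.scores.to_numpy(), f2.scores.to_numpy(),
                                   atol=1e-8)

    def test_retention_non_increasing_in_threshold(self, default_population):
        _, phenotypes, _ = default_population
        z = standardize(phenotypes)
        ks = [compute_factors(z, retention_threshold=th).n_retained
              for th in (0.5, 1.0, 2.0, 5.0)]
        assert ks == sorted(ks, reverse=True)

    def test_cumulative_variance_in_unit_interval(self, default_population):
        _, phenotypes, _ = default_population
        f = compute_factors(standardize(phenotypes))
        assert np.all(np.diff(f.variance_explained) > 0)
        assert 0 < f.variance_explained[-1] <= 1

    def test_nan_input_rejected(self):
        z = _frame([[1.0, 2.0], [np.nan, 0.5], [0.2, 0.1]])
        with pytest.raises(ValueError):
            compute_factors(z)

    def test_varimax_rotation_preserves_communalities(self, default_population):
        _, phenotypes, _ = default_population
        z = standardize(phenotypes)
        plain = compute_factors(z)
        rotated = compute_factors(z, rotate="varimax")
        np.testing.assert_allclose(
            (plain.loadings ** 2).sum(axis=1),
            (rotated.loadings ** 2).sum(axis=1), atol=1e-8)


def ward_linkage_oracle(points: np.ndarray) -> list[float]:
    """Brute-force Ward merge heights via the Lance-Williams recurrence.

    Works on squared Euclidean distances between singletons; returns the
    sqrt-scale merge heights in order, the convention scipy reports.
    """
    clusters = {i: 1 for i in range(len(points))}
    d2 = {}
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            d2[(i, j)] = float(np.sum((points[i] - points[j]) ** 2))
    heights = []
    next_id = len(points)
    while len(clusters) > 1:
        (s, t), best = min(d2.items(), key=lambda kv: kv[1])
        heights.append(np.sqrt(best))
        ns, nt = clusters.pop(s), clusters.pop(t)
        new = {}
        for v, nv in clusters.items():
            a, b = (min(v, s), max(v, s)), (min(v, t), max(v, t))
            dvs, dvt = d2[a], d2[b]
            dst = best
            new[v] = ((nv + ns) * dvs + (nv + nt) * dvt - nv * dst) / (nv + ns + nt)
        d2 = {k: val for k, val in d2.items() if s not in k and t not in k}
        for v, val in new.items():
            d2[(min(v, next_id), max(v, next_id))] = val
        clusters[next_id] = ns + nt
        next_id += 1
    return heights


class TestClusterPhenotypes:
    def test_linkage_matches_lance_williams_oracle(self):
        points = np.array([[0.0, 0.0], [1.0, 0.2], [0.4, 3.0],
                           [5.0, 5.0], [5.5, 4.5]])
        linkage, _ = cluster_phenotypes(_frame(points))
        np.testing.assert_allclose(linkage[:, 2], ward_linkage_oracle(points),
                                   rtol=1e-10)

    def test_merge_heights_monotone(self, default_population):
        _, phenotypes, _ = default_population
        linkage, _ = cluster_phenotypes(standardize(phenotypes))
        assert np.all(np.diff(linkage[:, 2]) >= -1e-12)

    def test_two_separated_blobs_split_perfectly(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 1.0, size=(30, 3))
        b = rng.normal(10.0, 1.0, size=(30, 3))
        df = _frame(np.vstack([a, b]))
        _, labels = cluster_phenotypes(df, n_clusters=2)
        assert labels.iloc[:30].nunique() == 1
        assert labels.iloc[30:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_two_points_merge_at_their_distance(self):
        df = _frame([[0.0, 0.0], [3.0, 4.0]])
        linkage, _ = cluster_phenotypes(df)
        assert linkage.shape[0] == 1
        assert linkage[0, 2] == pytest.approx(5.0)

    def test_duplicate_ids_rejected(self):
        df = _frame([[0, 1], [1, 0], [2, 2]])
        df.index = ["A", "A", "B"]
        with pytest.raises(ValueError, match="duplicate"):
            cluster_phenotypes(df)
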