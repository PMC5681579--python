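import itertools

import numpy as np
import pandas as pd
import pytest

from olfactomap import (
    DistanceRatioBootstrap,
    bootstrap_ratio_test,
    distance_ratio,
    lda_projection,
    pca_profiles,
)
from olfactomap.compare import pairwise_ratio_matrix


def brute_force_ratio(a, b):
    """Exhaustive pair enumeration oracle."""
    between = [np.linalg.norm(x - y) for x in a for y in b]
    within = [np.linalg.norm(x - y) for g in (a, b) for x, y in itertools.combinations(g, 2)]
    return np.mean(between) / np.mean(within)


class TestDistanceRatio:
    def test_1d_worked_example(self):
        a = np.array([[0.0], [2.0]])
        b = np.array([[1.0], [3.0]])
        # between mean (1+3+1+1)/4 = 1.5, within mean (2+2)/2 = 2
        assert distance_ratio(a, b) == pytest.approx(0.75)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.normal(size=(6, 3))
            b = rng.normal(size=(5, 3))
            assert distance_ratio(a, b) == pytest.approx(brute_force_ratio(a, b), rel=1e-12)

    def test_identical_point_sets(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(8, 4))
        assert distance_ratio(a, a.copy()) == pytest.approx(brute_force_ratio(a, a), rel=1e-12)

    def test_degenerate_groups_rejected(self):
        a = np.zeros((2, 2))
        b = np.ones((2, 2))
        with pytest.raises(ValueError):
            distance_ratio(a, b)  # all within-pair distances are zero

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(6, 3))
        b = rng.normal(size=(6, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = rng.normal(size=3)
        r0 = distance_ratio(a, b)
        r1 = distance_ratio(a @ q + shift, b @ q + shift)
        assert r1 == pytest.approx(r0, rel=1e-9)

    def test_monotone_in_separation(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(10, 4))
        b0 = rng.normal(size=(10, 4))
        ratios = []
        for sep in (0.0, 1.0, 2.0, 4.0, 8.0):
            b = b0.copy()
            b[:, 0] += sep
            ratios.append(distance_ratio(a, b))
        assert all(x < y for x, y in zip(ratios, ratios[1:]))

    def test_too_small_groups(self):
        with pytest.raises(ValueError):
            distance_ratio(np.zeros((1, 2)), np.ones((3, 2)))


class TestBootstrapRatioTest:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(10, 7)), rng.normal(size=(10, 7))
        r1 = bootstrap_ratio_test(a, b, n_boot=500, seed=11)
        r2 = bootstrap_ratio_test(a, b, n_boot=500, seed=11)
        assert r1 == r2

    def test_power_at_large_separation(self):
        # groups separated by 10x the within-group SD
        rng = np.random.default_rng(5)
        a = rng.normal(size=(10, 7))
        b = rng.normal(size=(10, 7))
        b[:, 0] += 10 * np.sqrt(2 * 7)
        _, p = bootstrap_ratio_test(a, b, n_boot=2000, seed=0)
        assert p < 0.01

    def test_null_rejection_rate_calibrated(self):
        # same-distribution species pairs: rejection at alpha=.05 near .05
        rng = np.random.default_rng(77)
        n_sims = 300
        rejections = 0
        for _ in range(n_sims):
            a = rng.normal(size=(10, 7))
            b = rng.normal(size=(10, 7))
            _, p = bootstrap_ratio_test(a, b, n_boot=500, seed=rng)
            rejections += p < 0.05
        assert rejections / n_sims == pytest.approx(0.05, abs=0.035)

    def test_percentile_variant_runs_and_is_conservative(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=(10, 7)), rng.normal(size=(10, 7))
        r, p = bootstrap_ratio_test(a, b, n_boot=500, seed=0, method="percentile")
        assert 0 < p <= 1 and r > 0

    def test_n_boot_floor(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError):
            bootstrap_ratio_test(rng.normal(size=(5, 2)), rng.normal(size=(5, 2)), n_boot=10)

    def test_estimator_fit_interface(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 3))
        y = np.array(["a"] * 10 + ["b"] * 10)
        est = DistanceRatioBootstrap(n_boot=200, random_state=0).fit(X, y)
        assert hasattr(est, "ratio_") and 0 <= est.p_value_ <= 1
        with pytest.raises(ValueError):
            DistanceRatioBootstrap(n_boot=200).fit(X, np.array(["a"] * 20))


class TestPairwiseMatrix:
    def test_symmetric_with_nan_diagonal(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("xyz"))
        df["species"] = ["s1"] * 4 + ["s2"] * 4 + ["s3"] * 4
        ratios, pvals = pairwise_ratio_matrix(df, n_boot=200, seed=0)
        assert np.isnan(np.diag(ratios)).all()
        np.testing.assert_allclose(ratios.values, ratios.values.T, equal_nan=True)
        off = ~np.eye(3, dtype=bool)
        assert np.isfinite(ratios.values[off]).all()
        assert ((pvals.values[off] > 0) & (pvals.values[off] <= 1)).all()


class TestLDA:
    def test_separates_distant_clouds(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, size=(20, 2))
        b = rng.normal(0, 1, size=(20, 2)) + [10.0, 0.0]  # 5-sigma+ separation
        coords, means, _ = lda_projection(
            np.vstack([a, b]), np.array(["a"] * 20 + ["b"] * 20), n_components=1
        )
        assert coords[:20, 0].max() < coords[20:, 0].min() or (
            coords[:20, 0].min() > coords[20:, 0].max()
        )
        assert means.shape[0] == 2

    def test_identical_groups_give_null_eigenvalues(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(15, 3))
        X = np.vstack([x, x])
        y = np.array(["a"] * 15 + ["b"] * 15)
        _, _, lda = lda_projection(X, y, n_components=1)
        # between-class scatter vanishes: discriminants explain ~nothing
        assert np.abs(lda.means_[0] - lda.means_[1]).max() < 1e-12

    def test_feature_permutation_equivariance(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 4))
        y = np.repeat(["a", "b", "c"], 10)
        c1, _, _ = lda_projection(X, y, n_components=2)
        perm = [2, 0, 3, 1]
        c2, _, _ = lda_projection(X[:, perm], y, n_components=2)
        # projections agree up to per-component sign
        for k in range(2):
            agree = np.allclose(c1[:, k], c2[:, k], atol=1e-8)
            flipped = np.allclose(c1[:, k], -c2[:, k], atol=1e-8)
            assert agree or flipped

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            lda_projection(np.zeros((5, 2)), np.array(["a"] * 5))

    def test_ridge_engages_when_wide(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(8, 12))  # features > n - groups
        y = np.array(["a"] * 4 + ["b"] * 4)
        coords, _, _ = lda_projection(X, y, n_components=1)
        assert np.all(np.isfinite(coords))


class TestPCAProfiles:
    def test_rank_one_data(self):
        rng = np.random.default_rng(14)
        v = rng.normal(size=50)
        v /= np.linalg.norm(v)
        scores = rng.normal(size=(10, 1))
        P = 0.3 + scores * v
        _, comps, evr = pca_profiles(P)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)
        assert abs(np.dot(comps[0], v)) == pytest.approx(1.0, abs=1e-3)

    def test_explained_variance_properties(self):
        rng = np.random.default_rng(15)
        P = rng.normal(size=(12, 30))
        _, _, evr = pca_profiles(P)
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rejects_nan_bins(self):
        P = np.ones((3, 5))
        P[1, 2] = np.nan
        with pytest.raises(ValueError):
            pca_profiles(P)
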