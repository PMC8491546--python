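"""Diversity, distance matrices and permutation tests, against closed forms,
brute-force enumeration and the scikit-bio implementations as oracles."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from forefield import succession_stats as st


class TestDiversity:
    def test_single_taxon(self):
        assert st.shannon([1, 0, 0]) == pytest.approx(0.0)
        assert st.inverse_simpson([1, 0, 0]) == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [2, 5, 50])
    def test_uniform_closed_forms(self, k):
        row = [1.0] * k
        assert st.shannon(row) == pytest.approx(math.log(k))
        assert st.inverse_simpson(row) == pytest.approx(k)

    def test_hand_computed_values(self):
        assert st.shannon([10, 5, 5]) == pytest.approx(
            -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        )
        assert st.inverse_simpson([0.5, 0.25, 0.25]) == pytest.approx(1 / 0.375)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            st.shannon([0, 0])
        with pytest.raises(ValueError):
            st.inverse_simpson([0, 0])

    def test_bounds_under_fuzzing(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            s = int(rng.integers(1, 30))
            row = rng.random(s) + 1e-6
            h = st.shannon(row)
            inv = st.inverse_simpson(row)
            assert 0 <= h <= math.log(s) + 1e-12
            assert 1 - 1e-12 <= inv <= s + 1e-9


class TestLowess:
    def test_constant_is_reproduced(self):
        x = np.arange(10.0)
        fitted = st.lowess_trend(x, np.full(10, 3.5))
        np.testing.assert_allclose(fitted, 3.5, atol=1e-9)

    def test_linear_is_reproduced(self):
        x = np.arange(20.0)
        y = 2.0 * x + 1.0
        np.testing.assert_allclose(st.lowess_trend(x, y), y, atol=1e-6)

    def test_recovers_noisy_monotone_curve(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 1, 100)
        truth = np.sqrt(x)
        y = truth + rng.normal(0, 0.05, 100)
        fitted = st.lowess_trend(x, y, span=0.4)
        interior = slice(10, 90)
        assert np.max(np.abs(fitted[interior] - truth[interior])) < 3 * 0.05 / math.sqrt(0.4 * 100) * 4

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            st.lowess_trend([1, 2], [1, 2])


class TestDistances:
    def test_identical_rows_zero(self):
        d = st.bray_curtis(np.array([[1, 2, 3], [1, 2, 3]]))
        assert d[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        d = st.bray_curtis(np.array([[1, 0], [0, 2]]))
        assert d[0, 1] == pytest.approx(1.0)

    def test_hand_formula(self):
        d = st.bray_curtis(np.array([[1, 2], [2, 1]]))
        assert d[0, 1] == pytest.approx(2 / 6)

    def test_two_zero_rows_defined_as_zero(self):
        d = st.bray_curtis(np.array([[0.0, 0.0], [0.0, 0.0]]))
        assert d[0, 1] == 0.0

    def test_negative_entries_raise(self):
        with pytest.raises(ValueError):
            st.bray_curtis(np.array([[-1.0, 2.0]]))

    def test_euclidean_matches_manual(self):
        d = st.euclidean(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d[0, 1] == pytest.approx(5.0)


def _random_distance(rng, n):
    x = rng.random((n, 3))
    return st.euclidean(x)


class TestPermanova:
    def test_r2_one_when_within_distances_zero(self):
        d = np.array(
            [
                [0, 0, 1, 1],
                [0, 0, 1, 1],
                [1, 1, 0, 0],
                [1, 1, 0, 0],
            ],
            dtype=float,
        )
        res = st.permanova(d, ["a", "a", "b", "b"], n_perm=99, seed=0)
        assert res.r2 == pytest.approx(1.0)

    def test_r2_plus_within_share_is_one(self):
        rng = np.random.default_rng(2)
        d = _random_distance(rng, 9)
        groups = ["a"] * 4 + ["b"] * 5
        res = st.permanova(d, groups, n_perm=99, seed=1)
        d2 = d**2
        ss_total = d2.sum() / (2 * 9)
        ss_within = 0.0
        for g in ("a", "b"):
            m = np.array(groups) == g
            ss_within += d2[np.ix_(m, m)].sum() / (2 * m.sum())
        assert res.r2 + ss_within / ss_total == pytest.approx(1.0)

    def test_statistic_matches_skbio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(3)
        d = _random_distance(rng, 12)
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        mine = st.permanova(d, groups, n_perm=99, seed=0)
        dm = skbio_stats.DistanceMatrix(d)
        theirs = skbio_stats.permanova(dm, groups, permutations=99)
        assert mine.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_two_group_1d_euclidean_equals_anova_f(self):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 10)
        x[5:] += 1.5
        d = st.euclidean(x.reshape(-1, 1))
        res = st.permanova(d, ["a"] * 5 + ["b"] * 5, n_perm=9, seed=0)
        assert res.pseudo_f == pytest.approx(f_oneway(x[:5], x[5:]).statistic, rel=1e-9)

    def test_p_floor_add_one_rule(self):
        rng = np.random.default_rng(5)
        d = _random_distance(rng, 8)
        res = st.permanova(d, ["a"] * 4 + ["b"] * 4, n_perm=99, seed=0)
        assert res.p >= 1 / 100

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            st.permanova(np.zeros((3, 3)), ["a", "a", "a"])

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(6)
        d = _random_distance(rng, 10)
        g = ["a"] * 5 + ["b"] * 5
        assert st.permanova(d, g, n_perm=199, seed=7) == st.permanova(d, g, n_perm=199, seed=7)


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        d = _random_distance(rng, 6)
        res = st.mantel(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        d1 = _random_distance(rng, 6)
        d2 = 2 * d1 + 0.1
        np.fill_diagonal(d2, 0)
        res = st.mantel(d1, d2, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_statistic_matches_skbio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(2)
        d1 = _random_distance(rng, 8)
        d2 = _random_distance(rng, 8)
        mine = st.mantel(d1, d2, n_perm=99, seed=0)
        r, _, _ = skbio_stats.mantel(
            skbio_stats.DistanceMatrix(d1), skbio_stats.DistanceMatrix(d2),
            permutations=0, alternative="greater",
        )
        assert mine.r == pytest.approx(r, rel=1e-9)

    def test_exact_p_matches_brute_force(self):
        rng = np.random.default_rng(3)
        d1 = _random_distance(rng, 5)
        d2 = _random_distance(rng, 5)
        res = st.mantel(d1, d2, exact=True)
        # independent brute force over all 120 relabelings
        i, j = np.tril_indices(5, k=-1)
        v1 = d1[i, j]
        count = 0
        for perm in permutations(range(5)):
            dp = d2[np.ix_(perm, perm)]
            r = np.corrcoef(v1, dp[i, j])[0, 1]
            count += r >= res.r - 1e-12
        assert res.p == pytest.approx(count / 120)

    def test_size_mismatch_raises(self):
        with pytest.raises(ValueError):
            st.mantel(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_constant_triangle_raises(self):
        d = np.ones((4, 4)) - np.eye(4)
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="constant"):
            st.mantel(d, _random_distance(rng, 4))


class TestSpearmanPerm:
    def test_monotone_extremes(self):
        x = np.arange(8.0)
        assert st.spearman_perm(x, x**3 + 1, n_perm=99, seed=0).rs == pytest.approx(1.0)
        assert st.spearman_perm(x, -x, n_perm=99, seed=0).rs == pytest.approx(-1.0)

    def test_midrank_ties_match_scipy(self):
        from scipy.stats import spearmanr

        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [3.0, 1.0, 4.0, 4.0, 5.0, 9.0]
        res = st.spearman_perm(x, y, n_perm=99, seed=0)
        assert res.rs == pytest.approx(spearmanr(x, y).statistic, rel=1e-12)

    def test_exact_p_matches_brute_force_with_ties(self):
        from scipy.stats import rankdata

        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 1.0, 4.0, 3.0, 5.0])  # tie pair in y
        res = st.spearman_perm(x, y, exact=True)
        rx = rankdata(x)
        ry = rankdata(y)

        def rho(a, b):
            a = a - a.mean()
            b = b - b.mean()
            return (a * b).sum() / np.sqrt((a**2).sum() * (b**2).sum())

        obs = rho(rx, ry)
        assert res.rs == pytest.approx(obs, rel=1e-12)
        count = sum(
            abs(rho(rx, ry[list(p)])) >= abs(obs) - 1e-12
            for p in permutations(range(6))
        )
        assert res.p == pytest.approx(count / 720)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError):
            st.spearman_perm([1, 1, 1], [1, 2, 3])


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(5.0)
        res = st.linear_fit(x, 2 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.r2 == pytest.approx(1.0)

    def test_matches_normal_equations(self):
        x = np.array([0.0, 1.0, 2.0, 4.0, 7.0])
        y = np.array([1.0, 2.0, 2.5, 5.0, 6.5])
        res = st.linear_fit(x, y)
        A = np.vstack([x, np.ones_like(x)]).T
        slope, intercept = np.linalg.solve(A.T @ A, A.T @ y)
        assert res.slope == pytest.approx(slope, rel=1e-12)
        assert res.intercept == pytest.approx(intercept, rel=1e-12)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 1000)
        y = rng.normal(0, 1, 1000)
        res = st.linear_fit(x, y)
        assert abs(res.slope) < 0.1
        assert res.r2 < 0.01

    def test_constant_x_raises(self):
        with pytest.raises(ValueError):
            st.linear_fit([1, 1, 1], [1, 2, 3])


class TestPca:
    def test_single_varying_feature_explains_everything(self):
        x = np.column_stack([np.arange(10.0), np.full(10, 2.0)])
        _, _, varexp = st.pca(x)
        assert varexp[0] == pytest.approx(1.0)

    def test_two_by_two_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (50, 2))
        x[:, 1] = 0.5 * x[:, 0] + 0.3 * x[:, 1]
        _, _, varexp = st.pca(x)
        cov = np.cov(x, rowvar=False)
        tr, det = cov.trace(), np.linalg.det(cov)
        lam1 = (tr + math.sqrt(tr**2 - 4 * det)) / 2
        assert varexp[0] == pytest.approx(lam1 / tr, rel=1e-9)

    def test_variance_explained_sums_to_one(self):
        rng = np.random.default_rng(2)
        _, _, varexp = st.pca(rng.normal(0, 1, (20, 6)))
        assert varexp.sum() == pytest.approx(1.0)
        assert (varexp >= 0).all()

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (15, 4))
        _, load1, _ = st.pca(x)
        _, load2, _ = st.pca(x.copy())
        np.testing.assert_allclose(load1, load2)
        for k in range(load1.shape[1]):
            assert load1[np.argmax(np.abs(load1[:, k])), k] > 0


class TestDistanceBins:
    @pytest.mark.parametrize(
        "d,label",
        [
            (0, "0-50"),
            (200, "150-250"),
            (50, "50-150"),       # half-open boundary
            (999.9, "750-1,000"),
            (1000, "1,000-1,250"),
            (3000, "2,000-4,000"),
            (10000, ">10,000"),
            (25000, ">10,000"),
        ],
    )
    def test_bin_membership(self, d, label):
        assert st.bin_distance(d) == label

    def test_negative_distance_raises(self):
        with pytest.raises(ValueError):
            st.bin_distance(-1)

    def test_bins_partition_nonnegative_axis(self):
        rng = np.random.default_rng(0)
        for d in rng.uniform(0, 30000, 500):
            assert st.bin_distance(float(d)) in st.BIN_LABELS


class TestGoScreen:
    def _matrix(self, rng, n=30, k=10):
        return pd.DataFrame(
            rng.random((n, k)), columns=[f"GO:{i + 1:07d}" for i in range(k)]
        )

    def test_injected_column_retained_with_rs_one(self):
        rng = np.random.default_rng(0)
        m = self._matrix(rng)
        covariate = np.arange(30.0)
        m["GO:0000001"] = covariate
        out = st.screen_go_correlations(m, covariate, n_perm=199, seed=1)
        assert "GO:0000001" in set(out["go_id"])
        assert out.set_index("go_id").loc["GO:0000001", "rs"] == pytest.approx(1.0)

    def test_threshold_is_strict(self):
        rng = np.random.default_rng(1)
        m = self._matrix(rng, n=100, k=2)
        covariate = np.arange(100.0)
        # engineer a column with rs exactly 0.4: impossible directly; instead
        # verify the retention rule on the returned table
        out = st.screen_go_correlations(m, covariate, r_threshold=0.0, alpha=1.0, n_perm=99, seed=0)
        strict = st.screen_go_correlations(m, covariate, r_threshold=1.0, alpha=1.0, n_perm=99, seed=0)
        assert len(strict) == 0  # |rs| > 1.0 can never hold (strict inequality)
        assert set(out.columns) == {"go_id", "rs", "p", "sign"}

    def test_constant_column_skipped_not_error(self):
        rng = np.random.default_rng(2)
        m = self._matrix(rng, k=3)
        m["GO:0000002"] = 1.0
        out = st.screen_go_correlations(m, np.arange(30.0), n_perm=99, seed=0)
        assert "GO:0000002" not in set(out["go_id"])
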