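"""CCC, NDR, stability calls, Bland–Altman, ICC, JSD, group comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fluorad import agreement as ag

finite_vec = arrays(
    np.float64,
    st.integers(3, 12),
    elements=st.floats(-1e3, 1e3, allow_nan=False, width=32),
)


class TestCCC:
    def test_perfect_agreement(self):
        assert ag.ccc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0, abs=1e-12)

    def test_perfect_negative_agreement(self):
        # mirrored vectors: cov = -sigma^2, means equal -> exactly -1
        assert ag.ccc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0, abs=1e-12)

    def test_shifted_vector_hand_value(self):
        # sigma12 = 2/3, sigma1^2 = sigma2^2 = 2/3, bias^2 = 1 -> 4/7
        assert ag.ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4 / 7, abs=1e-12)

    def test_symmetry(self, rng):
        x, y = rng.random(20), rng.random(20)
        assert ag.ccc(x, y) == pytest.approx(ag.ccc(y, x), abs=1e-14)

    def test_identical_constants_agree_perfectly(self):
        assert ag.ccc([5.0, 5.0, 5.0], [5.0, 5.0, 5.0]) == 1.0

    def test_degenerate_mismatch_reports_zero(self):
        assert ag.ccc([5.0, 5.0], [5.0, 5.0 + 0e0]) == 1.0  # still identical
        # non-identical constants have nonzero bias -> denominator > 0
        assert ag.ccc([5.0, 5.0], [6.0, 6.0]) == pytest.approx(0.0)

    def test_ccc_bounded_by_pearson(self, rng):
        for _ in range(50):
            x = rng.normal(size=12)
            y = 0.5 * x + rng.normal(size=12) + rng.normal()
            r = np.corrcoef(x, y)[0, 1]
            assert abs(ag.ccc(x, y)) <= abs(r) + 1e-12

    def test_equals_pearson_for_matched_moments(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        y = x[::-1].copy()  # same mean and variance
        assert ag.ccc(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_joint_permutation_invariance(self, rng):
        x, y = rng.random(15), rng.random(15)
        perm = rng.permutation(15)
        assert ag.ccc(x[perm], y[perm]) == pytest.approx(ag.ccc(x, y), abs=1e-14)

    def test_attenuation_decreases_ccc(self, rng):
        # y = lambda·x + noise: concordance falls as lambda departs from 1
        x = rng.normal(0, 1, 3000)
        noise = rng.normal(0, 0.05, 3000)
        cccs = [ag.ccc(x, lam * x + noise) for lam in (1.0, 0.8, 0.6, 0.4)]
        assert all(a > b for a, b in zip(cccs, cccs[1:]))

    def test_needs_two_observations(self):
        with pytest.raises(ValueError):
            ag.ccc([1.0], [1.0])


class TestNDR:
    def test_identical_vectors_give_one(self, rng):
        x = rng.random(10)
        assert ag.ndr(x, x.copy()) == 1.0

    def test_hand_value(self):
        # pooled range 10; mean |diff| relative = (0.1 + 0.1)/2
        assert ag.ndr([0.0, 10.0], [1.0, 9.0]) == pytest.approx(0.9, abs=1e-12)

    def test_zero_range_is_undefined(self):
        assert np.isnan(ag.ndr([3.0, 3.0], [3.0, 3.0]))

    def test_affine_invariance(self, rng):
        x, y = rng.random(12), rng.random(12)
        assert ag.ndr(3.5 * x - 2, 3.5 * y - 2) == pytest.approx(ag.ndr(x, y), abs=1e-12)

    def test_never_exceeds_one(self, rng):
        for _ in range(50):
            x, y = rng.random(8), rng.random(8)
            assert ag.ndr(x, y) <= 1.0


class TestStatisticInvariants:
    @given(x=finite_vec)
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_ccc_bounds_and_self_agreement(self, x):
        y = x + 1.0  # shared shape by construction
        c = ag.ccc(x, y)
        assert -1.0 - 1e-9 <= c <= 1.0 + 1e-9
        assert ag.ccc(x, x.copy()) == pytest.approx(1.0) or np.ptp(x) == 0

    @given(x=finite_vec, scale=st.floats(0.1, 50), shift=st.floats(-100, 100))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_ndr_affine_invariance_property(self, x, scale, shift):
        y = x[::-1].copy()
        a = ag.ndr(x, y)
        b = ag.ndr(scale * x + shift, scale * y + shift)
        if np.isnan(a):
            assert np.isnan(b)
        else:
            assert b == pytest.approx(a, abs=1e-6)


class TestStabilityCall:
    def test_boundary_inclusive(self):
        assert ag.stability_call(0.85, 0.90)

    def test_ccc_below_cutoff_unstable(self):
        assert not ag.stability_call(0.849, 0.99)

    def test_nan_fails(self):
        assert not ag.stability_call(float("nan"), 0.95)
        assert not ag.stability_call(0.95, float("nan"))

    def test_threshold_grid_monotone(self, rng):
        cccs = rng.uniform(-1, 1, 300)
        ndrs = rng.uniform(0, 1, 300)
        grid_c = np.linspace(0.75, 0.90, 7)
        grid_n = np.linspace(0.85, 0.95, 5)
        counts = np.array(
            [
                [np.sum((cccs >= c) & (ndrs >= n)) for n in grid_n]
                for c in grid_c
            ]
        )
        assert (np.diff(counts, axis=0) <= 0).all()
        assert (np.diff(counts, axis=1) <= 0).all()

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ag.stability_call(0.9, 0.9, ccc_min=0.0)


class TestBlandAltman:
    def test_identical_vectors_collapse(self):
        out = ag.bland_altman(np.arange(5.0), np.arange(5.0))
        assert out["bias"] == 0.0
        assert out["loa_low"] == out["loa_high"] == 0.0

    def test_constant_offset_is_bias(self):
        x = np.arange(10.0)
        out = ag.bland_altman(x + 2.5, x)
        assert out["bias"] == pytest.approx(2.5, abs=1e-12)

    def test_reference_band_covers_95pc_at_expected_ccc(self, rng):
        # simulate pairs whose true concordance is the band's own 0.85
        n = 10_000
        sigma = 1.0
        rho = 0.85
        cov = [[sigma, rho * sigma], [rho * sigma, sigma]]
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        out = ag.bland_altman(xy[:, 0], xy[:, 1], expected_ccc=0.85)
        inside = np.mean(np.abs(out["diff"]) <= out["reference_band"])
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError):
            ag.bland_altman([1.0, 2.0], [1.0, 2.0])


class TestICC:
    def test_identical_reads_give_one(self):
        reads = np.tile(np.array([1.0, 2.0, 5.0, 9.0]), (3, 1))
        assert ag.icc(reads) == pytest.approx(1.0)

    def test_independent_reads_near_zero(self, rng):
        reads = rng.normal(size=(2, 4000))
        assert abs(ag.icc(reads)) < 0.05

    def test_printed_toy_matrix_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        reads = np.array(
            [
                [9.0, 2.0, 5.0, 8.0, 6.0],
                [10.0, 4.0, 5.0, 7.0, 7.0],
                [8.0, 1.0, 4.0, 9.0, 5.0],
            ]
        )
        long = pd.DataFrame(
            {
                "reader": np.repeat(np.arange(3), 5),
                "item": np.tile(np.arange(5), 3),
                "score": reads.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="item", raters="reader", ratings="score")
        sel = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = ref.loc[sel, "ICC"].iloc[0]
        assert ag.icc(reads) == pytest.approx(icc2, abs=1e-9)

    def test_zero_item_variance_degenerate(self):
        reads = np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
        assert np.isnan(ag.icc(reads)) or ag.icc(reads) <= 0


class TestJSD:
    def test_identical_samples_zero(self, rng):
        x = rng.random(500)
        assert ag.js_divergence(x, x.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_maximal(self, rng):
        a = rng.uniform(0, 1, 1000)
        b = rng.uniform(5, 6, 1000)
        assert ag.js_divergence(a, b) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self, rng):
        a, b = rng.normal(0, 1, 400), rng.normal(0.5, 1.3, 400)
        assert ag.js_divergence(a, b) == pytest.approx(ag.js_divergence(b, a), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ag.js_divergence([], [1.0])


class TestCompareDistributions:
    def test_identical_groups_nonsignificant(self, rng):
        v = rng.normal(size=100)
        out = ag.compare_distributions({"a": v, "b": v.copy()})
        assert out["kruskal_p"] > 0.9
        assert all(p > 0.9 for p in out["group_vs_pool_p_adjusted"].values())

    def test_bh_stepup_arithmetic(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_label_permutation_leaves_statistic_unchanged(self, rng):
        groups = {"a": rng.normal(size=40), "b": rng.normal(1, 1, 40)}
        out1 = ag.compare_distributions(groups)
        out2 = ag.compare_distributions({"b": groups["b"], "a": groups["a"]})
        assert out1["kruskal_stat"] == pytest.approx(out2["kruskal_stat"])

    def test_small_groups_excluded(self, rng):
        out = ag.compare_distributions(
            {"a": rng.normal(size=30), "b": rng.normal(size=30), "tiny": [1.0, 2.0]}
        )
        assert out["excluded"] == ["tiny"]


class TestEvaluateFeatures:
    def test_pairwise_exclusion_of_missing_rows(self, rng):
        import pandas as pd

        t = pd.DataFrame({"f": rng.random(6)}, index=list("abcdef"))
        r = pd.DataFrame({"f": rng.random(5)}, index=list("abcde"))
        out = ag.evaluate_features(t, r)
        assert out.loc["f", "n"] == 5

    def test_mismatched_columns_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            ag.evaluate_features(pd.DataFrame({"a": [1]}), pd.DataFrame({"b": [1]}))
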