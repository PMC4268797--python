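"""Two-group statistics: t-tests, BH adjustment, rank AUC, bootstrap, ROC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirnome import diffexp
from mirnome.errors import DegenerateInputError, InputError
from conftest import make_annotation, make_matrix
import oracles


class TestTTest:
    def test_identical_groups_give_t_zero_p_one(self):
        t, p = diffexp.ttest_two_tailed([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_hand_example_matches_welch_formula(self):
        # mean diff -1, per-group variance 1, SE = sqrt(2/3)
        t, p = diffexp.ttest_two_tailed([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.0 / np.sqrt(2.0 / 3.0), abs=1e-12)
        t_ref, p_ref = oracles.welch_t_p([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-10)

    def test_swapping_groups_negates_t_keeps_p(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 9), rng.normal(0.5, 2, 14)
        t1, p1 = diffexp.ttest_two_tailed(x, y)
        t2, p2 = diffexp.ttest_two_tailed(y, x)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_pooled_variant_matches_oracle_df(self):
        # pooled t on equal-size groups coincides with scipy's equal_var form
        t, p = diffexp.ttest_two_tailed([1, 2, 3], [2, 3, 4], equal_var=True)
        assert t == pytest.approx(-1.2247448, abs=1e-6)

    @pytest.mark.parametrize(
        "x,y,exc",
        [
            ([1], [1, 2], InputError),
            ([1, 2], [np.nan, 2], InputError),
            ([2, 2, 2], [2, 2], DegenerateInputError),
        ],
    )
    def test_invalid_inputs_raise(self, x, y, exc):
        with pytest.raises(exc):
            diffexp.ttest_two_tailed(x, y)


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "p_min,expected",
        [(5.6e-19, "4.7e-16"), (2.2e-17, "1.9e-14")],
    )
    def test_worked_examples_848_features(self, p_min, expected):
        p = np.array([p_min] + [0.5] * 847)
        adj = diffexp.benjamini_hochberg(p)
        assert f"{adj.min():.1e}" == expected

    def test_single_p_value_unchanged(self):
        assert diffexp.benjamini_hochberg([0.03])[0] == pytest.approx(0.03)

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan, 0.5]):
            with pytest.raises(InputError):
                diffexp.benjamini_hochberg(bad)

    @settings(max_examples=120, derandomize=True)
    @given(st.lists(st.floats(1e-12, 1.0, exclude_min=False), min_size=1, max_size=12))
    def test_matches_stepup_oracle(self, p):
        adj = diffexp.benjamini_hochberg(p)
        np.testing.assert_allclose(adj, oracles.bh_stepup(p), rtol=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(1e-6, 1, 40)
        perm = rng.permutation(40)
        np.testing.assert_allclose(
            diffexp.benjamini_hochberg(p)[perm], diffexp.benjamini_hochberg(p[perm])
        )


class TestAuc:
    def test_hand_example_with_tie(self):
        oriented, auc, direction = diffexp.auc_mann_whitney([3, 4, 5], [1, 2, 3])
        assert oriented == pytest.approx(8.5 / 9)
        assert auc == pytest.approx(8.5 / 9) and direction == "up"

    def test_identical_multisets_give_half(self):
        oriented, auc, direction = diffexp.auc_mann_whitney([1, 2, 2], [1, 2, 2])
        assert oriented == 0.5 and auc == 0.5 and direction == "none"

    def test_perfect_separation(self):
        _, auc, _ = diffexp.auc_mann_whitney([10, 11], [1, 2, 3])
        assert auc == 1.0

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            n1 = int(rng.integers(1, 21))
            n2 = int(rng.integers(1, min(20, 400 // n1) + 1))
            c = rng.integers(0, 6, n1).astype(float)  # many ties
            k = rng.integers(0, 6, n2).astype(float)
            oriented, _, _ = diffexp.auc_mann_whitney(c, k)
            assert oriented == pytest.approx(oracles.auc_paircount(c, k), abs=1e-12)

    def test_orientation_complement_identity(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            c, k = rng.normal(0, 1, 8), rng.integers(0, 3, 11).astype(float)
            a, _, _ = diffexp.auc_mann_whitney(c, k)
            b, _, _ = diffexp.auc_mann_whitney(k, c)
            assert a + b == pytest.approx(1.0, abs=1e-12)


class TestBootstrapCI:
    def test_separated_groups_degenerate_interval(self):
        lo, hi = diffexp.auc_bootstrap_ci([10, 11, 12], [1, 2, 3], n_boot=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_same_seed_reproduces_interval(self):
        rng = np.random.default_rng(1)
        c, k = rng.normal(1, 1, 30), rng.normal(0, 1, 30)
        assert diffexp.auc_bootstrap_ci(c, k, seed=5) == diffexp.auc_bootstrap_ci(
            c, k, seed=5
        )

    def test_invalid_args(self):
        with pytest.raises(InputError):
            diffexp.auc_bootstrap_ci([1, 2], [3, 4], n_boot=0)
        with pytest.raises(InputError):
            diffexp.auc_bootstrap_ci([1], [3, 4])


class TestRocCurve:
    def test_single_pair(self):
        fpr, tpr = diffexp.roc_curve([2], [1])
        assert fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1
        assert np.trapezoid(tpr, fpr) == pytest.approx(1.0)

    def test_all_ties_give_diagonal(self):
        fpr, tpr = diffexp.roc_curve([5, 5, 5], [5, 5])
        assert np.trapezoid(tpr, fpr) == pytest.approx(0.5)

    def test_area_equals_rank_auc(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            c = rng.integers(0, 5, rng.integers(2, 10)).astype(float)
            k = rng.integers(0, 5, rng.integers(2, 10)).astype(float)
            fpr, tpr = diffexp.roc_curve(c, k)
            oriented, _, _ = diffexp.auc_mann_whitney(c, k)
            assert np.trapezoid(tpr, fpr) == pytest.approx(oriented, abs=1e-12)


class TestRunComparison:
    def _toy(self, seed, n_case=40, n_ctrl=40, n_feat=50, shift_row=None, shift=0.0):
        ann = make_annotation({"disease": n_case, "normal": n_ctrl})
        rng = np.random.default_rng(seed)
        X = rng.normal(10, 2, (n_feat, n_case + n_ctrl))
        if shift_row is not None:
            X[shift_row, :n_case] += shift
        return make_matrix(X, ann), ann

    def test_overlapping_selectors_rejected(self):
        matrix, ann = self._toy(0)
        with pytest.raises(InputError):
            diffexp.run_comparison(matrix, ann, "disease", ["disease", "normal"])

    def test_null_data_yields_no_significant_features(self):
        matrix, ann = self._toy(1, n_feat=848)
        res = diffexp.run_comparison(matrix, ann, "disease", "controls")
        assert res["significant"].sum() == 0
        # median fold changes cluster at 1 under the null
        assert np.median(res["fold_change"]) == pytest.approx(1.0, abs=0.05)

    def test_planted_downshift_is_recovered(self):
        # delta/sigma = 1.5 at n = 94 vs 900: overwhelming power
        ann = make_annotation({"disease": 94, "normal": 900})
        rng = np.random.default_rng(2)
        X = rng.normal(10, 2, (100, 994))
        X[0, :94] -= 3.0
        matrix = make_matrix(X, ann)
        res = diffexp.run_comparison(matrix, ann, "disease", "controls")
        row = res[res["feature_id"] == "f0"].iloc[0]
        assert row["direction"] == "down" and row["p_adjusted"] < 0.05
        assert row["auc_oriented"] < 0.5 < row["auc"]

    def test_fold_change_reciprocal_under_swap(self):
        matrix, ann = self._toy(3, shift_row=2, shift=4.0)
        a = diffexp.run_comparison(matrix, ann, "disease", "controls")
        b = diffexp.run_comparison(matrix, ann, "controls", "disease")
        np.testing.assert_allclose(
            a["fold_change"].to_numpy(), 1.0 / b["fold_change"].to_numpy()
        )

    def test_excluded_samples_left_out_of_pooled_comparison(self):
        ann = make_annotation(
            {"disease": 20, "others": 10, "normal": 20}, excluded=("others",)
        )
        rng = np.random.default_rng(4)
        matrix = make_matrix(rng.normal(10, 2, (5, 50)), ann)
        res = diffexp.run_comparison(matrix, ann, "all-disease", "controls")
        # "others" excluded: case side has 20 samples, so a direct comparison
        # against the explicit label must agree exactly
        direct = diffexp.run_comparison(matrix, ann, "disease", "controls")
        np.testing.assert_allclose(res["t_statistic"], direct["t_statistic"])

    def test_bootstrap_ci_columns_filled_when_requested(self):
        matrix, ann = self._toy(5, n_feat=4, shift_row=0, shift=5.0)
        res = diffexp.run_comparison(
            matrix, ann, "disease", "controls", n_boot=200, seed=1
        )
        assert res["ci_low"].notna().all()
        assert (res["ci_low"] <= res["ci_high"]).all()
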