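"""Specificity profiles, balloon tabulation, marker calling, pairwise signatures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirnome import cross_disease, diffexp
from mirnome.cross_disease import PairwiseSignature
from mirnome.errors import InputError
from conftest import make_annotation, make_matrix


def two_disease_fixture(seed=0):
    """Feature f0 planted up in A, down in B; 30 features of noise."""
    ann = make_annotation({"normal": 40, "A": 40, "B": 40})
    rng = np.random.default_rng(seed)
    X = rng.normal(10, 1, (30, 120))
    X[0, 40:80] += 4.0
    X[0, 80:120] -= 4.0
    return make_matrix(X, ann), ann


class TestProfiles:
    def test_opposite_directions_give_one_one_profile(self):
        matrix, ann = two_disease_fixture()
        prof = cross_disease.per_disease_profiles(matrix, ann)
        assert prof.counts.loc["f0", "n_up"] == 1
        assert prof.counts.loc["f0", "n_down"] == 1
        assert prof.signif.loc["f0", "A"] == 1 and prof.signif.loc["f0", "B"] == -1

    def test_null_data_gives_empty_profiles(self):
        ann = make_annotation({"normal": 40, "A": 40, "B": 40})
        rng = np.random.default_rng(1)
        matrix = make_matrix(rng.normal(10, 1, (100, 120)), ann)
        prof = cross_disease.per_disease_profiles(matrix, ann)
        assert (prof.counts.to_numpy() == 0).all()

    def test_undersized_disease_skipped_with_warning(self):
        ann = make_annotation({"normal": 20, "A": 20, "tiny": 1})
        rng = np.random.default_rng(2)
        matrix = make_matrix(rng.normal(10, 1, (10, 41)), ann)
        with pytest.warns(UserWarning, match="tiny"):
            prof = cross_disease.per_disease_profiles(matrix, ann)
        assert prof.diseases == ["A"] and prof.skipped[0][0] == "tiny"


class TestBalloon:
    def test_hand_counts(self):
        counts = pd.DataFrame(
            {"n_up": [8, 8, 0], "n_down": [0, 0, 8]}, index=["a", "b", "c"]
        )
        tab = cross_disease.balloon_table(counts, min_total=8)
        cells = {(r.n_down, r.n_up): r.count for r in tab.itertuples()}
        assert cells == {(0, 8): 2, (8, 0): 1}

    def test_all_null_profiles_give_empty_table(self):
        counts = pd.DataFrame({"n_up": [0, 0], "n_down": [0, 0]})
        assert cross_disease.balloon_table(counts, min_total=8).empty

    def test_conservation_of_qualifying_profiles(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            {"n_up": rng.integers(0, 12, 300), "n_down": rng.integers(0, 12, 300)}
        )
        tab = cross_disease.balloon_table(counts, min_total=8)
        qualifying = (counts.n_up + counts.n_down >= 8).sum()
        assert tab["count"].sum() == qualifying


class TestGeneralMarkers:
    def test_consistent_profile_called_with_direction(self):
        counts = pd.DataFrame({"n_up": [10], "n_down": [0]}, index=["m"])
        out = cross_disease.call_general_markers(counts, min_diseases=8)
        assert out.iloc[0]["feature_id"] == "m" and out.iloc[0]["direction"] == "up"

    def test_inconsistent_profile_rejected_unless_allowed(self):
        counts = pd.DataFrame({"n_up": [10], "n_down": [1]}, index=["m"])
        assert cross_disease.call_general_markers(counts).empty
        relaxed = cross_disease.call_general_markers(counts, require_consistent=False)
        assert len(relaxed) == 1

    def test_threshold_is_parametric(self):
        counts = pd.DataFrame({"n_up": [7], "n_down": [0]}, index=["m"])
        assert cross_disease.call_general_markers(counts, min_diseases=8).empty
        assert len(cross_disease.call_general_markers(counts, min_diseases=7)) == 1


class TestPairwise:
    def test_three_classes_give_three_signatures(self):
        matrix, ann = two_disease_fixture()
        sigs = cross_disease.pairwise_signatures(matrix, ann)
        assert len(sigs) == 3
        pairs = {(s.class_a, s.class_b) for s in sigs}
        assert pairs == {("normal", "A"), ("normal", "B"), ("A", "B")}

    def test_double_counting_identity(self):
        matrix, ann = two_disease_fixture()
        sigs = cross_disease.pairwise_signatures(matrix, ann)
        cc = cross_disease.comparison_counts(sigs)
        assert cc.sum() == sum(s.n_significant for s in sigs)

    def test_uniqueness_matches_quadratic_oracle(self):
        rng = np.random.default_rng(4)
        sigs = []
        for i in range(60):
            feats = frozenset(f"f{j}" for j in rng.choice(30, rng.integers(0, 6)))
            sigs.append(PairwiseSignature(f"a{i}", f"b{i}", feats))
        flags = cross_disease.signature_uniqueness(sigs)
        for s in sigs:
            expected = (
                sum(1 for o in sigs if o.significant_features == s.significant_features)
                == 1
            )
            assert flags[(s.class_a, s.class_b)] == expected

    def test_identical_sets_flagged_non_unique(self):
        s1 = PairwiseSignature("a", "b", frozenset({"x"}))
        s2 = PairwiseSignature("c", "d", frozenset({"x"}))
        flags = cross_disease.signature_uniqueness([s1, s2])
        assert flags == {("a", "b"): False, ("c", "d"): False}

    def test_empty_sets_not_unique_when_repeated(self):
        s1 = PairwiseSignature("a", "b", frozenset())
        s2 = PairwiseSignature("c", "d", frozenset())
        assert not any(cross_disease.signature_uniqueness([s1, s2]).values())


class TestSetOverlapAndCorrelation:
    def test_overlap_partitions_union(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = set(rng.choice(40, rng.integers(0, 20), replace=False).tolist())
            b = set(rng.choice(40, rng.integers(0, 20), replace=False).tolist())
            only_a, shared, only_b = cross_disease.set_overlap(a, b)
            assert only_a == len(a - b) and shared == len(a & b) and only_b == len(b - a)
            assert only_a + shared + only_b == len(a | b)

    def test_overlap_trivial_cases(self):
        assert cross_disease.set_overlap({1, 2}, {1, 2}) == (0, 2, 0)
        assert cross_disease.set_overlap({1}, {2, 3}) == (1, 0, 2)

    def _records(self, aucs):
        return pd.DataFrame(
            {"feature_id": [f"f{i}" for i in range(len(aucs))], "auc_oriented": aucs}
        )

    def test_identical_records_correlate_perfectly(self):
        r = self._records([0.5, 0.6, 0.7, 0.8, 0.55])
        assert cross_disease.auc_correlation(r, r) == pytest.approx(1.0)

    def test_anticorrelated_records(self):
        a = self._records([0.5, 0.6, 0.7, 0.8])
        b = self._records([1 - x for x in [0.5, 0.6, 0.7, 0.8]])
        assert cross_disease.auc_correlation(a, b) == pytest.approx(-1.0)

    def test_hand_computed_five_points(self):
        x = np.array([0.51, 0.62, 0.58, 0.71, 0.66])
        y = np.array([0.49, 0.65, 0.61, 0.70, 0.60])
        a, b = self._records(x), self._records(y)
        expected = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert cross_disease.auc_correlation(a, b) == pytest.approx(expected, abs=1e-12)

    def test_mismatched_feature_sets_rejected(self):
        a = self._records([0.5, 0.6])
        b = self._records([0.5, 0.6, 0.7])
        with pytest.raises(InputError):
            cross_disease.auc_correlation(a, b)


class TestAnova:
    def test_equal_group_means_give_zero_f(self):
        ann = make_annotation({"normal": 3, "A": 3})
        matrix = make_matrix(np.array([[1.0, 2, 3, 1, 2, 3]]), ann)
        res = cross_disease.anova_across_classes(matrix, ann)
        assert res.loc[0, "f_statistic"] == pytest.approx(0.0)
        assert res.loc[0, "p_raw"] == pytest.approx(1.0)
        assert res.loc[0, "stable"]

    def test_two_group_anova_equals_pooled_t_test(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            x = rng.normal(0, 1, rng.integers(3, 12))
            y = rng.normal(0.5, 1, rng.integers(3, 12))
            f_p = stats.f_oneway(x, y).pvalue
            _, t_p = diffexp.ttest_two_tailed(x, y, equal_var=True)
            assert f_p == pytest.approx(t_p, rel=1e-9)

    def test_global_null_significant_fraction_bounded(self):
        ann = make_annotation({"normal": 30, "A": 30, "B": 30})
        rng = np.random.default_rng(7)
        matrix = make_matrix(rng.normal(10, 1, (2000, 90)), ann)
        res = cross_disease.anova_across_classes(matrix, ann)
        assert (res["p_raw"] < 0.05).mean() <= 0.05 + 0.02
        assert res["stable"].mean() > 0.9

    def test_planted_shifts_break_stability(self):
        matrix, ann = two_disease_fixture()
        res = cross_disease.anova_across_classes(matrix, ann).set_index("feature_id")
        assert not res.loc["f0", "stable"]
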