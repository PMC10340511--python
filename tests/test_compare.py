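"""Rank-based comparisons, BH adjustment and the family-level scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from redundohist import bh_adjust, compare_k_groups, compare_two_groups
from redundohist.compare import family_comparison


class TestMannWhitney:
    def test_fully_separated_small_samples_exact_p(self):
        # brute force over all C(6,3)=20 rank assignments: two-sided p = 2/20
        res = compare_two_groups([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.1)

    def test_identical_groups_are_null(self):
        res = compare_two_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == pytest.approx(1.0)
        assert res.fold_change == pytest.approx(1.0)

    def test_large_shift_has_tiny_p(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 50)
        res = compare_two_groups(a + 1000, a)
        assert res.p < 1e-10

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            compare_two_groups([], [1.0])

    def test_fold_change_undefined_when_a_mean_is_zero(self):
        res = compare_two_groups([0.0, 0.0], [1.0, 2.0])
        assert res.fold_change is None

    @given(
        a=st.lists(st.floats(min_value=0.1, max_value=100), min_size=2, max_size=8),
        b=st.lists(st.floats(min_value=0.1, max_value=100), min_size=2, max_size=8),
    )
    @settings(derandomize=True, max_examples=50)
    def test_fold_change_antisymmetry(self, a, b):
        fc_ab = compare_two_groups(a, b).fold_change
        fc_ba = compare_two_groups(b, a).fold_change
        assert fc_ab == pytest.approx(1 / fc_ba)


class TestKruskalWallis:
    def test_hand_computed_h_without_ties(self):
        # rank sums 3, 7, 11 -> H = 12/(6*7) * (9+49+121)/2 - 21 = 32/7
        res = compare_k_groups({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        assert res.statistic == pytest.approx(32 / 7)

    def test_three_identical_groups_degenerate(self):
        res = compare_k_groups({"a": [2.0, 2.0], "b": [2.0, 2.0], "c": [2.0, 2.0]})
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_two_group_case_consistent_with_mann_whitney(self):
        a = [1.1, 3.4, 5.2, 7.9, 9.0]
        b = [2.0, 4.5, 6.6, 8.1, 10.5]
        kw = compare_k_groups({"a": a, "b": b})
        mw = compare_two_groups(a, b)
        # same hypothesis: orderings agree, p-values close up to the
        # chi-squared vs exact-enumeration approximation
        assert (kw.p < 0.05) == (mw.p < 0.05)
        assert abs(kw.p - mw.p) < 0.15

    def test_dunn_runs_only_when_significant(self):
        rng = np.random.default_rng(1)
        null_groups = {k: rng.normal(0, 1, 10) for k in "abc"}
        shifted = {"a": rng.normal(0, 1, 20), "b": rng.normal(5, 1, 20),
                   "c": rng.normal(10, 1, 20)}
        assert compare_k_groups(shifted).dunn is not None
        weak = compare_k_groups(null_groups)
        if weak.p >= 0.05:
            assert weak.dunn is None

    def test_dunn_flags_the_separated_pair(self):
        rng = np.random.default_rng(2)
        groups = {"lo": rng.normal(0, 1, 25), "mid": rng.normal(0.2, 1, 25),
                  "hi": rng.normal(8, 1, 25)}
        res = compare_k_groups(groups)
        dunn = res.dunn.set_index(["group_a", "group_b"])
        assert dunn.loc[("lo", "hi"), "q"] < 0.01
        assert dunn.loc[("lo", "mid"), "q"] > 0.05


class TestBenjaminiHochberg:
    def test_step_up_rule_by_hand(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_passes_through(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_order_preserved_with_input(self):
        p = [0.5, 0.001, 0.04, 0.9]
        q = bh_adjust(p)
        assert q[1] == min(q)
        assert list(np.argsort(q)) == list(np.argsort([0.5, 0.001, 0.04, 0.9]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _rates_frame(rng, cancer_types, families, n_per=6, scale=None):
    rows = []
    for ct in cancer_types:
        for fam in families:
            mult = (scale or {}).get(fam, 1.0)
            for i in range(n_per):
                rows.append({"cancer_type": ct, "family": fam,
                             "r": mult * rng.lognormal(0, 0.5),
                             "is_histone": True,
                             "protein_accession": f"{fam}{i}"})
    return pd.DataFrame(rows)


class TestFamilyComparison:
    FAMILIES = ["H1", "H2A", "H2B", "H3", "H4"]

    def _totals(self, cancer_types, override=None):
        rows = []
        for ct in cancer_types:
            for fam in self.FAMILIES:
                m = (override or {}).get((ct, fam), 50)
                rows.append({"cancer_type": ct, "family": fam, "m_total": m})
        return pd.DataFrame(rows)

    def test_low_count_cancer_type_excluded_with_reason(self):
        rng = np.random.default_rng(3)
        rates = _rates_frame(rng, ["ca_ok", "ca_low"], self.FAMILIES)
        totals = self._totals(["ca_ok", "ca_low"],
                              override={("ca_low", "H4"): 9})
        table, skipped = family_comparison(rates, totals, min_mutations=10)
        assert list(table["cancer_type"]) == ["ca_ok"]
        assert skipped[0]["cancer_type"] == "ca_low"
        assert skipped[0]["families"] == {"H4": 9}

    def test_scaled_family_detected(self):
        rng = np.random.default_rng(4)
        rates = _rates_frame(rng, ["ca"], self.FAMILIES, n_per=30,
                             scale={"H3": 10.0})
        table, _ = family_comparison(rates, self._totals(["ca"]))
        assert table["q"].iloc[0] < 0.05
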