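import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

import picarch as pc
from picarch.annotations import ValidationError

from conftest import make_track, region


def _table(**cols):
    df = pd.DataFrame(cols)
    df.index = [f"r{i}" for i in range(len(df))]
    df.index.name = "region_id"
    return df


class TestQuantifyOccupancy:
    def test_constant_track_gives_constant_both_methods(self):
        tr = make_track(np.full(1000, 2.0), bin_size=5, chrom_len=5000)
        rs = region(start=1000, end=2000, anchor=1500)
        for method in ("summit_height", "window_mean"):
            s = pc.quantify_occupancy(tr, rs, method=method)
            assert s.iloc[0] == pytest.approx(2.0)

    def test_doubling_track_doubles_occupancy(self):
        rng = np.random.default_rng(4)
        vals = rng.random(1000)
        rs = region(start=1000, end=2000, anchor=1500)
        for method in ("summit_height", "window_mean"):
            a = pc.quantify_occupancy(make_track(vals, 5, chrom_len=5000), rs,
                                      method)
            b = pc.quantify_occupancy(make_track(2 * vals, 5, chrom_len=5000),
                                      rs, method)
            assert b.iloc[0] == pytest.approx(2 * a.iloc[0])

    def test_window_mean_dilutes_impulse(self):
        x = np.zeros(1000)
        x[300] = 10.0  # impulse at the anchor
        tr = make_track(x, bin_size=5, chrom_len=5000)
        rs = region(start=1000, end=2000, anchor=1500)
        wm = pc.quantify_occupancy(tr, rs, "window_mean", window=200).iloc[0]
        sh = pc.quantify_occupancy(tr, rs, "summit_height").iloc[0]
        # smoothing spreads the impulse: summit height is below the raw
        # impulse but well above the windowed mean, which dilutes it ~1/80
        assert wm < sh < 10.0
        assert wm == pytest.approx(10.0 / 81, rel=0.05)

    def test_unknown_method_rejected(self):
        tr = make_track(np.ones(10), bin_size=1)
        with pytest.raises(ValidationError, match="method"):
            pc.quantify_occupancy(tr, region(end=10), method="banana")


class TestRankMostActive:
    def test_descending_selection(self):
        tab = _table(TBP=[5.0, 3.0, 9.0])
        assert list(pc.rank_most_active(tab, "TBP", 2)) == ["r2", "r0"]

    def test_top_n_equal_to_size_is_identity_set(self):
        tab = _table(TBP=[5.0, 3.0, 9.0])
        assert set(pc.rank_most_active(tab, "TBP", 3)) == set(tab.index)

    def test_tie_broken_lexicographically(self):
        tab = _table(TBP=[4.0, 4.0])
        assert list(pc.rank_most_active(tab, "TBP", 1)) == ["r0"]

    def test_invalid_arguments(self):
        tab = _table(TBP=[1.0, 2.0, 3.0])
        with pytest.raises(ValidationError):
            pc.rank_most_active(tab, "TBP", 0)
        with pytest.raises(ValidationError):
            pc.rank_most_active(tab, "nope", 1)


class TestCorrelate:
    def test_exact_linear_relation(self):
        tab = _table(A=[1.0, 2.0, 5.0], B=[2.0, 4.0, 10.0])
        assert pc.correlate(tab, "A", "B", scale="linear").pearson_r == \
            pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        tab = _table(A=[1.0, 2.0, 3.0], B=[1.0, 3.0, 2.0])
        assert pc.correlate(tab, "A", "B", scale="linear").pearson_r == \
            pytest.approx(0.5)

    def test_constant_column_rejected(self):
        tab = _table(A=[1.0, 1.0, 1.0], B=[1.0, 2.0, 3.0])
        with pytest.raises(ValidationError, match="variance"):
            pc.correlate(tab, "A", "B", scale="linear")

    def test_log_scale_invariant_to_positive_scaling(self):
        rng = np.random.default_rng(8)
        a, b = rng.lognormal(0, 1, 50), rng.lognormal(0, 1, 50)
        r1 = pc.correlate(_table(A=a, B=b), "A", "B", pseudocount=1e-12).pearson_r
        r2 = pc.correlate(_table(A=7 * a, B=b), "A", "B", pseudocount=1e-12).pearson_r
        assert r1 == pytest.approx(r2, abs=1e-9)


class TestRatioAnalysis:
    def test_median_centering_example(self):
        tab = _table(N=[2.0, 4.0, 8.0], D=[1.0, 1.0, 1.0])
        res = pc.ratio_analysis(tab, "N", "D", pseudocount=1e-9)
        np.testing.assert_allclose(res["normalized_ratio"], [0.5, 1.0, 2.0],
                                   rtol=1e-6)

    def test_equal_ratios_all_normal(self):
        tab = _table(N=[2.0, 4.0, 8.0], D=[1.0, 2.0, 4.0])
        res = pc.ratio_analysis(tab, "N", "D", pseudocount=1e-9)
        assert (res["group"] == "normal").all()
        np.testing.assert_allclose(res["normalized_ratio"], 1.0, rtol=1e-6)

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.floats(0.0, 1e4), min_size=3, max_size=60),
           st.lists(st.floats(0.0, 1e4), min_size=3, max_size=60))
    def test_median_of_normalized_ratios_is_one(self, num, den):
        n = min(len(num), len(den))
        tab = _table(N=num[:n], D=den[:n])
        res = pc.ratio_analysis(tab, "N", "D", pseudocount=0.1)
        assert np.median(res["normalized_ratio"]) == pytest.approx(1.0, abs=1e-9)

    def test_group_cuts_on_log2_scale(self):
        tab = _table(N=[1.0, 1.0, 1.0, 8.0, 0.125], D=[1.0] * 5)
        res = pc.ratio_analysis(tab, "N", "D", pseudocount=1e-9,
                                high_cut=1.0, low_cut=1.0)
        assert list(res["group"]) == ["normal"] * 3 + ["high", "low"]

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValidationError):
            pc.ratio_analysis(_table(N=[1.0], D=[1.0]), "N", "D")


class TestDecileSummary:
    def test_monotone_response_gives_monotone_medians(self):
        x = np.arange(20, dtype=float)
        tab = _table(TBP=x)
        res = pc.decile_summary(tab, "TBP", pd.Series(x ** 2, index=tab.index))
        assert (np.diff(res["response_median"]) > 0).all()
        assert set(res["n"]) == {2}

    def test_constant_response_constant_medians(self):
        tab = _table(TBP=np.arange(30, dtype=float))
        res = pc.decile_summary(tab, "TBP",
                                pd.Series(5.0, index=tab.index))
        assert (res["response_median"] == 5.0).all()

    def test_sizes_differ_by_at_most_one(self):
        tab = _table(TBP=np.arange(23, dtype=float))
        res = pc.decile_summary(tab, "TBP",
                                pd.Series(1.0, index=tab.index))
        assert res["n"].max() - res["n"].min() <= 1
        assert res["n"].sum() == 23

    def test_too_few_regions_rejected(self):
        tab = _table(TBP=np.arange(5, dtype=float))
        with pytest.raises(ValidationError):
            pc.decile_summary(tab, "TBP", pd.Series(1.0, index=tab.index))


class TestGroupOverlap:
    def test_identical_sets(self):
        out = pc.group_overlap({"a", "b"}, {"a", "b"}, {"a", "b", "c"})
        assert out == {"a_only": 0, "b_only": 0, "both": 2, "neither": 1}

    def test_disjoint_sets(self):
        out = pc.group_overlap({"a"}, {"b"}, {"a", "b", "c"})
        assert out["both"] == 0

    def test_enumerated_example(self):
        universe = set(range(10))
        out = pc.group_overlap({1, 2, 3}, {2, 3, 4}, universe)
        assert (out["a_only"], out["b_only"], out["both"], out["neither"]) \
            == (1, 1, 2, 6)
        assert sum(out.values()) == len(universe)

    def test_element_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            pc.group_overlap({"z"}, set(), {"a"})


def _enumerate_upper_tail(N, K, n, k):
    """Exhaustive oracle: fraction of n-subsets of an N-universe (K labeled)
    with at least k labeled members."""
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return hits / total


class TestLabelEnrichment:
    def test_matches_exhaustive_enumeration(self):
        labels = pd.Series(["lab"] * 4 + [""] * 6,
                           index=[f"r{i}" for i in range(10)])
        group = [f"r{i}" for i in [0, 1, 2, 5, 6]]  # k=3 labeled of n=5
        res = pc.label_enrichment(group, labels.index, labels)
        row = res.set_index("label").loc["lab"]
        assert row.p == pytest.approx(66 / 252)
        assert row.p == pytest.approx(_enumerate_upper_tail(10, 4, 5, 3))
        assert row.fold == pytest.approx((3 / 5) / (4 / 10))

    @pytest.mark.parametrize("N,K,n", [(8, 3, 4), (12, 5, 6), (9, 2, 3)])
    def test_hypergeometric_tail_equals_enumeration(self, N, K, n):
        for k in range(0, min(K, n) + 1):
            assert float(hypergeom.sf(k - 1, N, K, n)) == \
                pytest.approx(_enumerate_upper_tail(N, K, n, k))

    def test_zero_overlap_has_p_one(self):
        labels = pd.Series(["lab", "lab", "", ""],
                           index=["r0", "r1", "r2", "r3"])
        res = pc.label_enrichment(["r2", "r3"], labels.index, labels)
        assert res.set_index("label").loc["lab"].p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        labels = pd.Series([""], index=["r0"])
        with pytest.raises(ValidationError):
            pc.label_enrichment([], labels.index, labels)

    def test_bh_adjustment_present_and_monotone(self):
        rng = np.random.default_rng(3)
        labs = ["a", "b", "c", ""]
        labels = pd.Series(rng.choice(labs, 40),
                           index=[f"r{i}" for i in range(40)])
        res = pc.label_enrichment([f"r{i}" for i in range(10)],
                                  labels.index, labels)
        assert (res["p_bh"] >= res["p"] - 1e-12).all()
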