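import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proxifilter.core import (
    FP,
    TP,
    UNANNOTATED,
    RankedColumn,
    analyze_table,
    apply_cutoff,
    compute_auc,
    compute_curve,
    find_cutoff,
    intersect,
    rank_column,
    top_enriched,
)
from proxifilter.errors import AnalysisError
from proxifilter.io_tables import RatioTable, ReferenceSet

from .conftest import cumulative_rates, mann_whitney_auc, random_ranked


def make_ranked(labels, ratios=None):
    n = len(labels)
    if ratios is None:
        ratios = np.arange(n, 0, -1, dtype=float)
    return RankedColumn(
        column_name="c",
        accessions=np.array([f"P{i}" for i in range(n)], dtype=object),
        ratios=np.asarray(ratios, dtype=float),
        labels=np.asarray(labels, dtype=object),
    )


class TestRankColumn:
    def test_sort_and_labels(self, toy_table, toy_ref):
        r = rank_column(toy_table, "R1", toy_ref)
        assert list(r.accessions) == ["P1", "P2", "P3", "P4", "P5"]
        assert list(r.labels) == [TP, FP, TP, UNANNOTATED, FP]
        assert r.n_tp == 2 and r.n_fp == 2

    def test_no_reference_overlap(self, toy_table):
        ref = ReferenceSet(tp=frozenset({"X1"}), fp=frozenset({"X2"}))
        with pytest.raises(AnalysisError):
            rank_column(toy_table, "R1", ref)

    def test_stable_tie_order(self, toy_ref):
        table = RatioTable(
            pd.DataFrame(
                {"R1": [3.0, 3.0, 5.0]},
                index=pd.Index(["P2", "P1", "P3"], name="accession"),
            )
        )
        r = rank_column(table, "R1", toy_ref)
        # P2 precedes P1 because it came first in the file
        assert list(r.accessions) == ["P3", "P2", "P1"]

    def test_missing_cells_excluded(self, toy_ref):
        table = RatioTable(
            pd.DataFrame(
                {"R1": [5.0, np.nan, 3.0, 1.0]},
                index=pd.Index(["P1", "P2", "P3", "P5"], name="accession"),
            )
        )
        r = rank_column(table, "R1", toy_ref)
        assert "P2" not in set(r.accessions)
        assert len(r) == 3

    def test_unknown_column(self, toy_table, toy_ref):
        with pytest.raises(KeyError):
            rank_column(toy_table, "nope", toy_ref)


class TestComputeCurve:
    def test_worked_example(self, toy_ranked):
        c = compute_curve(toy_ranked)
        assert np.allclose(c.tpr, [0.5, 0.5, 1, 1, 1])
        assert np.allclose(c.fpr, [0, 0.5, 0.5, 0.5, 1])
        assert np.allclose(c.diff, [0.5, 0, 0.5, 0.5, 0])

    def test_separated(self):
        c = compute_curve(make_ranked([TP, TP, FP, FP]))
        assert np.allclose(c.tpr, [0.5, 1, 1, 1])
        assert np.allclose(c.fpr, [0, 0, 0.5, 1])
        assert np.allclose(c.diff, [0.5, 1, 0.5, 0])

    def test_two_element(self):
        c = compute_curve(make_ranked([FP, TP]))
        assert np.allclose(c.tpr, [0, 1])
        assert np.allclose(c.fpr, [1, 1])
        assert np.allclose(c.diff, [-1, 0])

    def test_diff_identity(self, toy_ranked):
        c = compute_curve(toy_ranked)
        assert np.array_equal(c.diff, c.tpr - c.fpr)

    def test_last_rates_are_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = compute_curve(random_ranked(rng))
            assert c.tpr[-1] == 1.0 and c.fpr[-1] == 1.0
            assert np.all(np.diff(c.tpr) >= 0) and np.all(np.diff(c.fpr) >= 0)


class TestFindCutoff:
    def test_tie_takes_last(self):
        assert find_cutoff([0.5, 0, 0.5, 0.5, 0], "last") == 4

    def test_tie_takes_first(self):
        assert find_cutoff([0.5, 0, 0.5, 0.5, 0], "first") == 1

    def test_unique_max(self):
        assert find_cutoff([0.5, 1, 0.5, 0]) == 2

    def test_nonpositive_max(self):
        assert find_cutoff([-1, 0]) == 2

    def test_empty(self):
        with pytest.raises(ValueError):
            find_cutoff([])


class TestComputeAuc:
    def test_worked_example(self, toy_ranked):
        auc, pts = compute_auc(toy_ranked)
        assert auc == pytest.approx(0.75, abs=1e-12)
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)

    def test_extremes(self):
        assert compute_auc(make_ranked([TP, TP, FP, FP]))[0] == 1.0
        assert compute_auc(make_ranked([FP, FP, TP, TP]))[0] == 0.0

    def test_single_tie_pair(self):
        auc, _ = compute_auc(make_ranked([TP, FP], ratios=[2.0, 2.0]))
        assert auc == pytest.approx(0.5, abs=1e-12)

    def test_tie_order_irrelevant(self):
        # same (ratio, label) multiset, tie block in either display order
        a = compute_auc(make_ranked([TP, FP, TP, FP], ratios=[3, 2, 2, 1]))[0]
        b = compute_auc(make_ranked([TP, TP, FP, FP], ratios=[3, 2, 2, 1]))[0]
        assert a == b == pytest.approx(0.875, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_oracle_equivalence(self, seed):
        ranked = random_ranked(np.random.default_rng(seed))
        auc, _ = compute_auc(ranked)
        expected = mann_whitney_auc(list(ranked.ratios), list(ranked.labels))
        assert auc == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_rates_match_enumeration(self, seed):
        ranked = random_ranked(np.random.default_rng(seed))
        c = compute_curve(ranked)
        tpr, fpr = cumulative_rates(list(ranked.labels))
        assert np.array_equal(c.tpr, tpr)
        assert np.array_equal(c.fpr, fpr)


class TestMonotonicInvariance:
    @pytest.mark.parametrize(
        "transform", [np.exp, lambda x: x**3, lambda x: 10 * x], ids=["exp", "cube", "10x"]
    )
    def test_invariance(self, transform, toy_ref):
        rng = np.random.default_rng(3)
        values = rng.lognormal(0, 1, 40)
        accs = [f"P{i}" for i in range(40)]
        ref = ReferenceSet(tp=frozenset(accs[:10]), fp=frozenset(accs[10:20]))
        t1 = RatioTable(pd.DataFrame({"R1": values}, index=pd.Index(accs, name="accession")))
        t2 = RatioTable(
            pd.DataFrame({"R1": transform(values)}, index=pd.Index(accs, name="accession"))
        )
        c1 = compute_curve(rank_column(t1, "R1", ref))
        c2 = compute_curve(rank_column(t2, "R1", ref))
        assert list(c1.accessions) == list(c2.accessions)
        assert np.array_equal(c1.tpr, c2.tpr) and np.array_equal(c1.fpr, c2.fpr)
        assert c1.cutoff_rank == c2.cutoff_rank
        assert c1.auc == pytest.approx(c2.auc, abs=1e-12)


class TestApplyCutoff:
    def test_retains_unannotated(self, toy_ranked):
        c = compute_curve(toy_ranked)
        assert c.cutoff_rank == 4
        retained = apply_cutoff(toy_ranked, c.cutoff_rank)
        assert retained == {"P1", "P2", "P3", "P4"}  # P4 unannotated yet retained

    def test_full_and_singleton(self, toy_ranked):
        assert apply_cutoff(toy_ranked, 5) == {"P1", "P2", "P3", "P4", "P5"}
        assert apply_cutoff(toy_ranked, 1) == {"P1"}

    @pytest.mark.parametrize("k", [0, 6, -1])
    def test_out_of_range(self, toy_ranked, k):
        with pytest.raises(ValueError):
            apply_cutoff(toy_ranked, k)

    def test_size_equals_rank(self, toy_ranked):
        for k in range(1, 6):
            assert len(apply_cutoff(toy_ranked, k)) == k


class TestIntersect:
    def test_two_columns(self):
        r = intersect({"a": {"P1", "P2", "P3"}, "b": {"P2", "P3", "P4"}})
        assert r.final_proteome == {"P2", "P3"}

    def test_single_column_identity(self):
        r = intersect({"a": {"P1", "P2"}})
        assert r.final_proteome == {"P1", "P2"}

    def test_disjoint_warns(self, caplog):
        with caplog.at_level("WARNING"):
            r = intersect({"a": {"P1"}, "b": {"P2"}})
        assert r.final_proteome == frozenset()
        assert any("empty" in rec.message for rec in caplog.records)

    def test_subset_invariant(self):
        r = intersect({"a": {"P1", "P2"}, "b": {"P2", "P3"}, "c": {"P2"}})
        for retained in r.per_column_retained.values():
            assert r.final_proteome <= retained

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            intersect({})


class TestTopEnriched:
    def test_all_rows(self, toy_ranked):
        t = top_enriched(toy_ranked, 5)
        assert list(t["accession"]) == ["P1", "P2", "P3", "P4", "P5"]
        assert list(t["rank"]) == [1, 2, 3, 4, 5]

    def test_no_padding(self, toy_ranked):
        assert len(top_enriched(toy_ranked, 100)) == 5

    def test_single(self, toy_ranked):
        t = top_enriched(toy_ranked, 1)
        assert list(t["accession"]) == ["P1"]

    def test_invalid_n(self, toy_ranked):
        with pytest.raises(ValueError):
            top_enriched(toy_ranked, 0)


class TestAnalyzeTable:
    def test_end_to_end(self, toy_ref):
        table = RatioTable(
            pd.DataFrame(
                {"R1": [5.0, 4.0, 3.0, 2.0, 1.0], "R2": [5.0, 4.0, 3.0, 2.0, 1.0]},
                index=pd.Index(["P1", "P2", "P3", "P4", "P5"], name="accession"),
            )
        )
        curves, result, tops = analyze_table(table, toy_ref)
        assert [c.column_name for c in curves] == ["R1", "R2"]
        assert result.final_proteome == {"P1", "P2", "P3", "P4"}
        assert set(tops) == {"R1", "R2"}
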