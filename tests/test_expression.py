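"""Quality filtering, counting, FPKM/qPCR, exact test + BH against oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from spliceforge.expression import (
    CountsTable,
    bh_adjust,
    call_de,
    count_features,
    differential_intron_genes,
    exact_count_test,
    fpkm,
    overlap_summary,
    quality_filter,
    relative_qpcr,
)
from spliceforge.gene_model import Interval
from spliceforge.simulate import SimConfig, SimRead, make_reads


def read(seq, qual, intervals=(), name="r"):
    return SimRead(
        name=name,
        seq=seq,
        qual=list(qual),
        variant="v",
        tx_start=0,
        genome_intervals=[Interval(*iv) for iv in intervals],
    )


class TestQualityFilter:
    def test_high_quality_read_kept_untrimmed(self):
        kept, rep = quality_filter([read("A" * 50, [40] * 50)])
        assert rep.kept == 1 and rep.trimmed == 0 and len(kept[0].seq) == 50

    def test_read_below_70_percent_passing_removed(self):
        # 30 bases Q35 and 20 interspersed Q20 (ends on Q35, so no trimming)
        qual = [35, 20, 20, 35, 35] * 10
        kept, rep = quality_filter([read("A" * 50, qual)])
        assert rep.removed == 1 and not kept

    def test_low_quality_tail_trimmed(self):
        qual = [35] * 45 + [20] * 5
        kept, rep = quality_filter([read("A" * 50, qual, intervals=[(0, 50)])])
        assert rep.trimmed == 1
        assert len(kept[0].seq) == 45
        assert kept[0].genome_intervals == [Interval(0, 45)]

    def test_all_low_quality_removed_as_empty(self):
        kept, rep = quality_filter([read("AAAA", [10, 10, 10, 10])])
        assert rep.removed == 1 and not kept

    def test_quality_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            quality_filter([read("AAAA", [40] * 3)])

    def test_boundary_q30_counts_as_passing(self):
        kept, rep = quality_filter([read("A" * 10, [30] * 10)])
        assert rep.kept == 1 and len(kept[0].seq) == 10

    def test_simulated_low_quality_fraction_is_removed(self, cwp_model, cwp_variants):
        cfg = SimConfig(seed=4, depth=2000, low_quality_fraction=0.25)
        reads = make_reads(cwp_model, cwp_variants, {"VAR1": 1.0}, cfg)
        _, rep = quality_filter(reads)
        assert rep.removed / len(reads) == pytest.approx(0.25, abs=0.03)


class TestCountFeatures:
    def test_strict_assignment(self, cwp_model):
        i1 = cwp_model.introns[0]
        e1 = cwp_model.exons[0]
        reads = [
            read("A" * 10, [40] * 10, [(e1.start, e1.start + 10)], "exonic"),
            read("A" * 10, [40] * 10, [(i1.start + 5, i1.start + 15)], "intronic"),
            read("A" * 10, [40] * 10, [(i1.start - 5, i1.start + 5)], "straddle"),
            read("A" * 10, [40] * 10, [(e1.end - 5, e1.end), (i1.end, i1.end + 5)], "junction"),
        ]
        table, ambiguous = count_features({"s1": reads}, cwp_model, {"s1": "A"})
        assert table.counts.loc["cwp_like", "s1"] == 2  # exonic + junction
        assert table.counts.loc["cwp_like:intron1", "s1"] == 1
        assert ambiguous["s1"] == 1

    def test_pure_canonical_sample_has_zero_intron_counts(self, cwp_model, cwp_variants):
        cfg = SimConfig(seed=9, depth=1000, low_quality_fraction=0.0)
        reads = make_reads(cwp_model, cwp_variants, {"VAR1": 1.0}, cfg)
        table, _ = count_features({"s": reads}, cwp_model, {"s": "A"})
        introns = table.counts.loc[table.features["kind"] == "intron", "s"]
        assert (introns == 0).all()

    def test_library_size_covers_assigned_plus_ambiguous(self, cwp_model, cwp_variants):
        cfg = SimConfig(seed=9, depth=500, low_quality_fraction=0.0)
        reads = make_reads(cwp_model, cwp_variants, {"VAR2": 1.0}, cfg)
        table, amb = count_features({"s": reads}, cwp_model, {"s": "A"})
        assert table.library_sizes["s"] == table.counts["s"].sum() + amb["s"] == 500


class TestFpkm:
    def test_unit_case(self):
        assert fpkm(10, 1000, 1_000_000) == pytest.approx(10.0)
        assert fpkm(0, 1000, 1_000_000) == 0.0
        assert fpkm(58, 1000, 1_000_000) == pytest.approx(58.0)

    def test_zero_length_or_library_rejected(self):
        with pytest.raises(ValueError):
            fpkm(1, 0, 1e6)
        with pytest.raises(ValueError):
            fpkm(1, 1000, 0)

    @given(
        st.integers(0, 10000),
        st.integers(100, 5000),
        st.integers(10**5, 10**8),
        st.integers(2, 9),
    )
    @settings(max_examples=50, deadline=None)
    def test_linearity(self, count, length, lib, k):
        base = fpkm(count, length, lib)
        assert fpkm(k * count, length, lib) == pytest.approx(k * base)
        assert fpkm(count, k * length, lib) == pytest.approx(base / k)
        assert fpkm(count, length, k * lib) == pytest.approx(base / k)


class TestQpcr:
    def test_direct_substitution(self):
        assert relative_qpcr(2, 1000) == pytest.approx(2.0)
        assert relative_qpcr(0, 1000) == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_qpcr(1, 0)


def oracle_exact_test(ca, cb, la, lb):
    """Exhaustive enumeration over all splits of the pooled total."""
    total = ca + cb
    if total == 0:
        return 1.0
    p = la / (la + lb)
    pmf = stats.binom.pmf(np.arange(total + 1), total, p)
    observed = pmf[ca]
    return float(pmf[pmf <= observed * (1 + 1e-7)].sum())


class TestExactCountTest:
    def test_balanced_counts_equal_libraries_give_p_one(self):
        assert exact_count_test(5, 5, 1e6, 1e6) == pytest.approx(1.0)

    def test_extreme_imbalance_is_tiny(self):
        assert exact_count_test(0, 50, 1e6, 1e6) < 1e-10

    def test_both_zero_gives_one(self):
        assert exact_count_test(0, 0, 1e6, 1e6) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            exact_count_test(-1, 5, 1e6, 1e6)

    @given(
        st.integers(0, 200),
        st.integers(0, 200),
        st.floats(0.2, 5.0),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_enumeration_oracle(self, ca, cb, lib_ratio):
        if ca + cb > 200:
            cb = 200 - ca
        la, lb = 1e6 * lib_ratio, 1e6
        got = exact_count_test(ca, cb, la, lb)
        want = oracle_exact_test(ca, cb, la, lb)
        assert got == pytest.approx(want, rel=1e-6, abs=1e-12)

    @given(st.integers(0, 100), st.integers(0, 100), st.floats(0.5, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_under_condition_swap(self, ca, cb, r):
        la, lb = 1e6 * r, 1e6
        assert exact_count_test(ca, cb, la, lb) == pytest.approx(
            exact_count_test(cb, ca, lb, la), rel=1e-9
        )


def oracle_bh(p):
    """Textbook step-up formula: min over j>=i of (m/j) p_(j), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_all_equal_stay_equal(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=150, deadline=None)
    def test_matches_closed_form_oracle(self, p):
        assert bh_adjust(p) == pytest.approx(oracle_bh(p), rel=1e-12, abs=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_never_below_raw(self, p):
        assert (bh_adjust(p) >= np.asarray(p) - 1e-15).all()


def small_table(counts: dict, conditions: dict, kind: dict | None = None):
    df = pd.DataFrame(counts)
    features = pd.DataFrame(
        {
            "gene_id": [f.split(":")[0] for f in df.index],
            "kind": [kind.get(f, "gene") if kind else "gene" for f in df.index],
            "intron_index": None,
            "length": 1000,
        },
        index=df.index,
    )
    return CountsTable(
        counts=df,
        features=features,
        conditions=pd.Series(conditions),
        library_sizes=df.sum(axis=0),
    )


class TestCallDE:
    def test_conjunction_rule(self):
        # one strong true change plus many null genes so BH has context;
        # a ~3-fold change with tiny counts must not pass the adjusted-p gate
        rng = np.random.default_rng(0)
        null = rng.poisson(100, size=(40, 2))
        counts = {
            "A1": [3000, 6] + list(null[:, 0]),
            "B1": [300, 2] + list(null[:, 1]),
        }
        idx = ["big", "smallfc"] + [f"n{i}" for i in range(40)]
        table = small_table(
            {k: pd.Series(v, index=idx) for k, v in counts.items()},
            {"A1": "A", "B1": "B"},
        )
        res = call_de(table).table
        assert res.loc["big", "is_de"] and res.loc["big", "direction"] == "up"
        assert not res.loc["smallfc", "is_de"]

    def test_scaling_counts_and_libraries_preserves_calls(self):
        idx = [f"g{i}" for i in range(20)]
        rng = np.random.default_rng(1)
        a = rng.poisson(80, 20)
        b = a.copy()
        b[:3] = a[:3] * 6
        t1 = small_table(
            {"A1": pd.Series(a, index=idx), "B1": pd.Series(b, index=idx)},
            {"A1": "A", "B1": "B"},
        )
        t2 = small_table(
            {"A1": pd.Series(3 * a, index=idx), "B1": pd.Series(3 * b, index=idx)},
            {"A1": "A", "B1": "B"},
        )
        r1, r2 = call_de(t1).table, call_de(t2).table
        assert (r1["is_de"] == r2["is_de"]).all()

    def test_replicates_are_pooled_per_condition(self):
        idx = ["g"]
        t = small_table(
            {
                "A1": pd.Series([400], index=idx),
                "A2": pd.Series([420], index=idx),
                "B1": pd.Series([40], index=idx),
                "B2": pd.Series([45], index=idx),
            },
            {"A1": "A", "A2": "A", "B1": "B", "B2": "B"},
        )
        res = call_de(t).table
        assert res.loc["g", "p_value"] == pytest.approx(
            exact_count_test(820, 85, 820.0, 85.0)
        )


class TestIntronDE:
    def test_retention_shift_flags_gene_via_intron(self, cwp_model, cwp_variants):
        cfg = SimConfig(seed=12, depth=4000, low_quality_fraction=0.0)
        reads_a = make_reads(cwp_model, cwp_variants, {"VAR1": 1.0}, cfg, stream="a")
        reads_b = make_reads(
            cwp_model, cwp_variants, {"VAR1": 0.5, "VAR2": 0.5}, cfg, stream="b"
        )
        table, _ = count_features(
            {"a": reads_a, "b": reads_b}, cwp_model, {"a": "A", "b": "B"},
            mode="overlap",
        )
        assert differential_intron_genes(table) == {"cwp_like"}

    def test_identical_conditions_stay_unflagged(self, cwp_model, cwp_variants):
        cfg = SimConfig(seed=13, depth=4000, low_quality_fraction=0.0)
        mix = {"VAR1": 0.5, "VAR2": 0.5}
        reads_a = make_reads(cwp_model, cwp_variants, mix, cfg, stream="x")
        reads_b = make_reads(cwp_model, cwp_variants, mix, cfg, stream="y")
        table, _ = count_features(
            {"a": reads_a, "b": reads_b}, cwp_model, {"a": "A", "b": "B"},
            mode="overlap",
        )
        assert differential_intron_genes(table) == set()

    def test_gene_without_intron_features_never_flagged(self):
        t = small_table(
            {"A1": pd.Series([10], index=["g"]), "B1": pd.Series([500], index=["g"])},
            {"A1": "A", "B1": "B"},
        )
        assert differential_intron_genes(t) == set()


class TestOverlap:
    def test_disjoint_and_identical(self):
        assert overlap_summary({"a"}, {"b"}) == {"de_only": 1, "intron_only": 1, "both": 0}
        assert overlap_summary({"a", "b"}, {"a", "b"}) == {
            "de_only": 0,
            "intron_only": 0,
            "both": 2,
        }

    @given(
        st.sets(st.integers(0, 50), max_size=30),
        st.sets(st.integers(0, 50), max_size=30),
    )
    @settings(max_examples=50, deadline=None)
    def test_counts_sum_correctly(self, a, b):
        s = overlap_summary({str(x) for x in a}, {str(x) for x in b})
        assert s["de_only"] + s["both"] == len(a)
        assert s["intron_only"] + s["both"] == len(b)
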