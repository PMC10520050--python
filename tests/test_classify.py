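"""Class rules, fractional weighting, quantification, and profiles."""

import numpy as np
import pandas as pd
import pytest

from granulekit.classify import (
    G22_RULE,
    G26_RULE,
    UNASSIGNED,
    ClassRule,
    call_22g,
    call_26g,
    call_pirna,
    classify_all,
    length_firstnt_profile,
    quantify_genes,
)
from granulekit.readproc import Alignment, CollapsedRead


def _read(seq, count=1, rid="r1"):
    return CollapsedRead(rid, seq, count)


def _aln(start, strand="+", length=21, n_hits=1, rid="r1", contig="chrT"):
    return Alignment(rid, contig, start, strand, length, n_hits)


class TestPirnaRule:
    def test_offset_one_unique_sense_accepted(self, toy_index):
        # locus p1 spans [1000, 1021) on +; 5' end at 1001 -> offset 1
        read = _read("T" + "A" * 20)
        out = call_pirna(read, [_aln(1001)], toy_index)
        assert out is not None and out.cls == "piRNA"
        assert out.weights == {"p1": 1.0}

    def test_offset_on_minus_strand_locus(self, toy_index):
        # locus pm spans [1200, 1221) on -; its 5' end is 1220
        read = _read("T" + "A" * 20)
        out = call_pirna(read, [_aln(1198, strand="-")], toy_index)  # 5' = 1218, offset 2
        assert out is not None

    def test_offset_three_refused(self, toy_index):
        read = _read("T" + "A" * 20)
        assert call_pirna(read, [_aln(1003)], toy_index) is None

    def test_multimapper_refused(self, toy_index):
        read = _read("T" + "A" * 20)
        assert call_pirna(read, [_aln(1001, n_hits=2)], toy_index) is None

    def test_short_read_refused(self, toy_index):
        read = _read("T" + "A" * 13)
        assert call_pirna(read, [_aln(1001, length=14)], toy_index) is None

    def test_antisense_to_locus_refused(self, toy_index):
        read = _read("T" + "A" * 20)
        assert call_pirna(read, [_aln(1001, strand="-")], toy_index) is None

    def test_non_t_first_base_refused(self, toy_index):
        read = _read("G" + "A" * 20)
        assert call_pirna(read, [_aln(1001)], toy_index) is None


class TestG22Rule:
    def test_unique_antisense_full_weight(self, toy_index):
        read = _read("G" + "A" * 21)  # 22 nt
        out = call_22g(read, [_aln(3100, strand="-", length=22)], toy_index)
        assert out is not None
        # location overlaps the two stacked genes gB/gC -> split equally
        assert out.weights == {"gB": 0.5, "gC": 0.5}

    def test_rrna_precedence_takes_whole_location(self, toy_index):
        # location inside gA (+) also overlaps rRNA rr (+); read on - is
        # antisense to both; rRNA takes the full weight
        read = _read("G" + "A" * 21)
        out = call_22g(read, [_aln(2100, strand="-", length=22)], toy_index)
        assert out.weights == {"rr": 1.0}

    def test_24nt_refused(self, toy_index):
        read = _read("G" + "A" * 23)
        assert call_22g(read, [_aln(3100, strand="-", length=24)], toy_index) is None

    def test_5prime_c_refused(self, toy_index):
        read = _read("C" + "A" * 21)
        assert call_22g(read, [_aln(3100, strand="-", length=22)], toy_index) is None

    def test_multimap_feature_split_arithmetic(self, toy_index):
        """count=1, n_hits=4, one location over 2 features -> 1/4 x 1/2 each."""
        read = _read("G" + "A" * 21)
        alns = [
            _aln(3100, strand="-", length=22, n_hits=4),
            _aln(6000, strand="-", length=22, n_hits=4),
            _aln(7000, strand="-", length=22, n_hits=4),
            _aln(8000, strand="-", length=22, n_hits=4),
        ]
        out = call_22g(read, alns, toy_index)
        assert out.weights == pytest.approx({"gB": 0.125, "gC": 0.125})

    def test_sense_only_alignment_refused(self, toy_index):
        read = _read("G" + "A" * 21)
        assert call_22g(read, [_aln(3100, strand="+", length=22)], toy_index) is None


class TestG26Rule:
    def test_default_rule_antisense_mrna(self, toy_index):
        read = _read("G" + "A" * 25)  # 26 nt
        out = call_26g(read, [_aln(3100, strand="-", length=26)], toy_index)
        assert out is not None and out.cls == "26G"

    def test_5prime_a_refused_by_default(self, toy_index):
        read = _read("A" + "G" * 25)
        assert call_26g(read, [_aln(3100, strand="-", length=26)], toy_index) is None

    def test_rule_override_allows_5prime_a(self, toy_index):
        from dataclasses import replace

        rule = replace(G26_RULE, first_bases=frozenset("GA"))
        read = _read("A" + "G" * 25)
        out = call_26g(read, [_aln(3100, strand="-", length=26)], toy_index, rule)
        assert out is not None


class TestClassifyAll:
    def test_precedence_21g_read_is_22g(self, toy_index):
        """A 21 nt 5'G read cannot be piRNA (needs 5'T) and falls to 22G."""
        read = _read("G" + "A" * 20)
        out = classify_all(
            [read], {"r1": [_aln(3100, strand="-", length=21)]}, toy_index
        )
        assert out[0].cls == "22G"

    def test_empty_input_empty_output(self, toy_index):
        assert classify_all([], {}, toy_index) == []

    def test_unmatched_read_unassigned(self, toy_index):
        read = _read("C" + "A" * 20)
        out = classify_all([read], {"r1": [_aln(7000, length=21)]}, toy_index)
        assert out[0].cls == UNASSIGNED and out[0].weights == {}

    def test_weight_conservation_for_assigned(self, toy_index):
        reads = [
            _read("G" + "A" * 21, count=7, rid="a"),
            _read("T" + "A" * 20, count=3, rid="b"),
        ]
        alns = {
            "a": [_aln(3100, strand="-", length=22, rid="a")],
            "b": [_aln(1000, length=21, rid="b")],
        }
        for cr in classify_all(reads, alns, toy_index):
            assert cr.total_weight == pytest.approx(cr.count, rel=1e-9)

    def test_rrna_precedence_monotone(self, toy_annots, toy_index):
        """Adding an overlapping gene never decreases the rRNA's weight."""
        from granulekit.annotations import AnnotationSet, Feature, FeatureIndex

        read = _read("G" + "A" * 21)
        aln = [_aln(2100, strand="-", length=22)]
        with_overlap = call_22g(read, aln, toy_index).weights.get("rr", 0.0)
        solo = AnnotationSet(
            {"chrT": 10_000}, [Feature("rr", "chrT", 2050, 2200, "+", "rRNA")]
        )
        without = call_22g(read, aln, FeatureIndex(solo)).weights.get("rr", 0.0)
        assert with_overlap >= without

    def test_pure_function_repeatable(self, toy_index):
        read = _read("G" + "A" * 21)
        alns = {"r1": [_aln(3100, strand="-", length=22)]}
        a = classify_all([read], alns, toy_index)
        b = classify_all([read], alns, toy_index)
        assert a[0].weights == b[0].weights and a[0].cls == b[0].cls


class TestQuantify:
    def test_rpm_arithmetic(self, toy_index):
        reads = [_read("G" + "A" * 21, count=4)]
        alns = {"r1": [_aln(2300, strand="-", length=22)]}  # gA only (past rRNA)
        table = quantify_genes(classify_all(reads, alns, toy_index), depth=2000)
        assert table.rpm("22G")["gA"] == pytest.approx(2000.0)

    def test_total_rpm_linearity(self, toy_index):
        reads = [
            _read("G" + "A" * 21, count=4, rid="a"),
            _read("A" + "G" * 21, count=6, rid="b"),
        ]
        alns = {
            "a": [_aln(2300, strand="-", length=22, rid="a")],
            "b": [_aln(3100, strand="-", length=22, rid="b")],
        }
        table = quantify_genes(classify_all(reads, alns, toy_index), depth=5000)
        assert table.df["rpm"].sum() == pytest.approx(1e6 * 10 / 5000)

    def test_tsv_roundtrip(self, toy_index, tmp_path):
        from granulekit.classify import GeneCountTable

        reads = [_read("G" + "A" * 21, count=4)]
        alns = {"r1": [_aln(2300, strand="-", length=22)]}
        table = quantify_genes(classify_all(reads, alns, toy_index), depth=2000)
        path = tmp_path / "t.tsv"
        table.to_tsv(str(path))
        back = GeneCountTable.read_tsv(str(path))
        pd.testing.assert_frame_equal(back.df, table.df)
        assert back.depth == table.depth


class TestProfile:
    def test_single_cell_for_pure_input(self):
        prof = length_firstnt_profile([("T" + "A" * 20, 10)])
        assert prof.loc[21, "T"] == 10
        assert prof.to_numpy().sum() == 10

    def test_margins_reproduce_totals(self, rng):
        reads = []
        total = 0
        for _ in range(50):
            L = int(rng.integers(15, 41))
            count = int(rng.integers(1, 5))
            seq = "".join(rng.choice(list("ACGT"), L))
            reads.append((seq, count))
            total += count
        prof = length_firstnt_profile(reads)
        assert prof.to_numpy().sum() == total

    def test_class_mix_modes(self, genome, annots, sim_config, gindex):
        """A 50/50 piRNA/22G library peaks at (21, T) and (22, G or A)."""
        from dataclasses import replace

        from granulekit.synthdata import simulate_small_rna_reads

        cfg = replace(
            sim_config,
            class_mix={"piRNA": 0.5, "22G": 0.5, "26G": 0.0,
                       "structural": 0.0, "background": 0.0},
        )
        reads, _ = simulate_small_rna_reads(
            genome, annots, cfg, n_reads=10_000, genome_index=gindex
        )
        prof = length_firstnt_profile((r.sequence, 1) for r in reads)
        assert prof.loc[21, "T"] == pytest.approx(5000, abs=3 * 50)
        g22 = prof.loc[21:23, ["G", "A"]].to_numpy().sum()
        assert g22 == pytest.approx(5000, abs=3 * 50)
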