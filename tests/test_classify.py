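"""Tail classification: templated split, NT/ambiguous calls, categories."""

import pandas as pd
import pytest

from conftest import brute_force_classify, random_isomir_reads
from isotail.assign import CollapsedRead, assign_library, assign_read
from isotail.classify import (
    classify_isomir,
    classify_table,
    coarse_tail_label,
    split_templated,
    tail_category,
)
from isotail.simulate import knockout_panel_design, simulate_library


def _classify(catalog, read):
    a = assign_read(CollapsedRead(read, 1), catalog)
    assert a.assigned, read
    return classify_isomir(read, a.mirna, catalog, a.motif_start_in_read)


class TestSplitTemplated:
    def test_exact_mature(self, tiny_catalog):
        mir = tiny_catalog["mirX-5p"]
        anchor = tiny_catalog.motif_start["mirX-5p"]
        tl, tail = split_templated(
            mir.sequence, mir, mir.loci[0], anchor, anchor, tiny_catalog.motif_len
        )
        assert tail == ""
        assert tl == len(mir.sequence) - anchor - tiny_catalog.motif_len

    def test_fully_templated_extension(self, tiny_catalog):
        # locus L1 downstream starts with A: mature+"A" is entirely genomic
        mir = tiny_catalog["mirX-5p"]
        anchor = tiny_catalog.motif_start["mirX-5p"]
        tl, tail = split_templated(
            mir.sequence + "A", mir, mir.loci[0], anchor, anchor, tiny_catalog.motif_len
        )
        assert tail == ""
        assert tl == len(mir.sequence) - anchor - tiny_catalog.motif_len + 1

    def test_mismatch_at_first_downstream_base(self, tiny_catalog):
        # locus L1 downstream starts with A, so a C extension is the tail
        mir = tiny_catalog["mirX-5p"]
        anchor = tiny_catalog.motif_start["mirX-5p"]
        _, tail = split_templated(
            mir.sequence + "C", mir, mir.loci[0], anchor, anchor, tiny_catalog.motif_len
        )
        assert tail == "C"

    def test_inconsistent_anchor_is_error(self, tiny_catalog):
        mir = tiny_catalog["mirX-5p"]
        with pytest.raises(ValueError, match="anchor"):
            split_templated(mir.sequence, mir, mir.loci[0], 0, 4, tiny_catalog.motif_len)


class TestClassifyIsomir:
    def test_canonical(self, tiny_catalog):
        tc = _classify(tiny_catalog, tiny_catalog["mirX-5p"].sequence)
        assert (tc.end_status, tc.origin, tc.three_prime_offset) == ("canonical", "none", 0)

    def test_templated_extension_is_ambiguous(self, tiny_catalog):
        # "A" matches L1's downstream start
        tc = _classify(tiny_catalog, tiny_catalog["mirX-5p"].sequence + "A")
        assert tc.origin == "ambiguous"
        assert tc.category == "mono_A"
        assert tc.end_status == "tailed"

    def test_any_locus_rule(self, tiny_catalog):
        # "U" mismatches L1 ("AGG...") but matches L2 ("UGG...")
        tc = _classify(tiny_catalog, tiny_catalog["mirX-5p"].sequence + "U")
        assert tc.origin == "ambiguous"
        # mirY has a single locus starting with C, so "U" is non-templated
        tc2 = _classify(tiny_catalog, tiny_catalog["mirY-3p"].sequence + "U")
        assert tc2.origin == "NT" and tc2.category == "mono_U"

    def test_trimmed(self, tiny_catalog):
        tc = _classify(tiny_catalog, tiny_catalog["mirX-5p"].sequence[:-2])
        assert (tc.end_status, tc.three_prime_offset, tc.tail_seq) == ("trimmed", -2, "")

    def test_trimmed_then_retailed(self, tiny_catalog):
        seq = tiny_catalog["mirX-5p"].sequence
        read = seq[:-2] + "CC"  # mature ends ...GUU; replace last 2 with CC
        tc = _classify(tiny_catalog, read)
        assert tc.end_status == "trimmed_tailed"
        assert tc.origin == "NT" and tc.tail_seq == "CC"

    def test_partially_templated_extension_full_tail_default(self, tiny_catalog):
        # L1 downstream = AGG...: extension "AC" matches A then diverges
        seq = tiny_catalog["mirY-3p"].sequence  # single locus, downstream CCAAC...
        tc = _classify(tiny_catalog, seq + "CG")
        assert tc.origin == "NT"
        assert tc.tail_seq == "CG"  # full extension counts as the tail

    def test_nt_suffix_only_switch(self, tiny_catalog):
        seq = tiny_catalog["mirY-3p"].sequence
        a = assign_read(CollapsedRead(seq + "CG", 1), tiny_catalog)
        tc = classify_isomir(seq + "CG", a.mirna, tiny_catalog, a.motif_start_in_read, nt_suffix_only=True)
        assert tc.tail_seq == "G" and tc.origin == "NT"
        assert tc.three_prime_offset == 1  # the templated C credits the genome

    def test_overlong_tail_flagged(self, tiny_catalog):
        tc = _classify(tiny_catalog, tiny_catalog["mirY-3p"].sequence + "U" * 9)
        assert tc.flagged and tc.origin == "NT" and tc.category == "none"

    def test_monotone_consistency(self, catalog10):
        """Extending an ambiguous isomiR with the next genomic base keeps it
        ambiguous; a non-matching base makes it NT."""
        checked = 0
        for name in catalog10.names():
            mir = catalog10[name]
            loc = mir.loci[0]
            for ext_len in (1, 2, 3):
                ext = loc.downstream[:ext_len]
                read = mir.sequence + ext
                a = assign_read(CollapsedRead(read, 1), catalog10)
                if not a.assigned:
                    continue
                tc = classify_isomir(read, a.mirna, catalog10, a.motif_start_in_read)
                assert tc.origin == "ambiguous"
                bad = "A" if loc.downstream[ext_len] != "A" else "C"
                matches_other = any(
                    l.downstream[: ext_len + 1] == ext + bad for l in mir.loci
                )
                read2 = read + bad
                a2 = assign_read(CollapsedRead(read2, 1), catalog10)
                tc2 = classify_isomir(read2, a2.mirna, catalog10, a2.motif_start_in_read)
                assert tc2.origin == ("ambiguous" if matches_other else "NT")
                checked += 1
        assert checked >= 10

    def test_agrees_with_brute_force(self, catalog10):
        for read in random_isomir_reads(catalog10, 400, seed=5):
            a = assign_read(CollapsedRead(read, 1), catalog10)
            if not a.assigned:
                continue
            tc = classify_isomir(read, a.mirna, catalog10, a.motif_start_in_read)
            exp_status, exp_tail, exp_origin = brute_force_classify(
                read, a.mirna, catalog10, a.motif_start_in_read
            )
            assert (tc.end_status, tc.tail_seq, tc.origin) == (exp_status, exp_tail, exp_origin)

    def test_matches_simulator_truth_without_misreads(self, catalog10):
        design = knockout_panel_design(depth=5000, seed=9, misread_rate=0.0, a_to_g_rate=0.0)
        sim = simulate_library(catalog10, design, "WT", 1)
        la = assign_library(sim.reads, catalog10)
        table = classify_table(la.table, catalog10)
        truth = (
            sim.truth.groupby(["read", "mirna", "end_status", "origin", "coarse"])
            .size()
            .reset_index()
        )
        merged = table.merge(truth, left_on="sequence", right_on="read", suffixes=("", "_t"))
        assert len(merged) == len(table)
        assert (merged["end_status"] == merged["end_status_t"]).all()
        assert (merged["origin"] == merged["origin_t"]).all()


class TestTailCategory:
    @pytest.mark.parametrize(
        "tail,expected",
        [
            ("U", "mono_U"), ("A", "mono_A"), ("G", "mono_G"), ("C", "mono_C"),
            ("AA", "di_AA"), ("UU", "di_UU"), ("AU", "di_AU"), ("UA", "di_UA"),
            ("GC", "mixed"), ("UUU", "mixed"), ("AGU", "mixed"),
        ],
    )
    def test_category_table(self, tail, expected):
        assert tail_category(tail) == expected

    @pytest.mark.parametrize(
        "tail,expected",
        [("UUU", "U_tail"), ("AA", "A_tail"), ("GC", "Mixed"), ("AU", "Mixed"), ("G", "Mixed")],
    )
    def test_coarse_label(self, tail, expected):
        assert coarse_tail_label(tail) == expected

    def test_empty_tail_is_error(self):
        with pytest.raises(ValueError):
            tail_category("")


def test_partition_every_read_gets_one_class(catalog10):
    design = knockout_panel_design(depth=3000, seed=2)
    sim = simulate_library(catalog10, design, "WT", 1)
    la = assign_library(sim.reads, catalog10)
    table = classify_table(la.table, catalog10)
    assert table["end_status"].isin(["canonical", "trimmed", "tailed", "trimmed_tailed"]).all()
    tailed = table["tail_seq"] != ""
    assert (table.loc[tailed, "origin"] != "none").all()
    assert (table.loc[~tailed, "origin"] == "none").all()
    assert (table.loc[~tailed, "category"] == "none").all()


class TestTailProperties:
    """Property checks over arbitrary tails (derandomized hypothesis)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    tails = st.text(alphabet="ACGU", min_size=1, max_size=10)

    @settings(derandomize=True, max_examples=200)
    @given(tails)
    def test_category_and_coarse_are_consistent(self, tail):
        cat = tail_category(tail)
        coarse = coarse_tail_label(tail)
        if len(tail) == 1:
            assert cat == f"mono_{tail}"
        if coarse == "U_tail":
            assert set(tail) == {"U"}
        if coarse == "A_tail":
            assert set(tail) == {"A"}
        if set(tail) <= {"A", "U"} and len(tail) <= 2:
            assert cat != "mixed"
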