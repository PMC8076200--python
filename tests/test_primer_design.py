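import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as mt
from hypothesis import given, settings
from hypothesis import strategies as st

from indelmark.anchored_alignment import AnchoredMSA, MemberEvents
from indelmark.config import PipelineConfig
from indelmark.indel_screen import REF_MEMBER, IndelBlock
from indelmark.primer_design import (DesignFailure, PrimerPair,
                                     conserved_flank_windows,
                                     count_occurrences, decode_marker_name,
                                     design_primer_pair, melting_temp,
                                     name_marker, uniqueness_check)
from indelmark.seq_io import GenomeAssembly, GenomicInterval, revcomp
from conftest import random_dna

CFG = PipelineConfig()


class TestNaming:
    @pytest.mark.parametrize("chrom,pos,name", [
        (1, 302_000, "A01P00302"),
        (12, 27_058_000, "A12P27058"),
        (10, 0, "A10P00000"),
    ])
    def test_published_examples_and_padding(self, chrom, pos, name):
        assert name_marker(chrom, pos) == name

    @given(st.integers(1, 99), st.integers(0, 99_999_499))
    @settings(max_examples=100, deadline=None)
    def test_decode_is_lossless(self, chrom, pos):
        decoded = decode_marker_name(name_marker(chrom, pos))
        assert decoded == (chrom, round(pos / 1000))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            name_marker(0, 100)
        with pytest.raises(ValueError):
            name_marker(1, 100_000_000)
        with pytest.raises(ValueError):
            decode_marker_name("B01P00001")


class TestMeltingTemp:
    def test_gc_content_monotonicity(self):
        assert melting_temp("A" * 18) < melting_temp("GC" * 9)

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(71)
        for _ in range(20):
            s = random_dna(rng, int(rng.integers(15, 30)))
            assert melting_temp(s) == pytest.approx(
                melting_temp(revcomp(s)), abs=0.011)

    def test_matches_independent_nearest_neighbor_computation(self):
        """Cross-check the in-package NN sum against biopython's
        implementation with the same unified parameters."""
        rng = np.random.default_rng(72)
        for _ in range(40):
            s = random_dna(rng, int(rng.integers(15, 30)))
            expected = mt.Tm_NN(s, nn_table=mt.DNA_NN4, Na=50,
                                dnac1=250, dnac2=0, saltcorr=5)
            assert melting_temp(s) == pytest.approx(expected, abs=0.1)

    def test_ambiguity_and_length_rejected(self):
        with pytest.raises(ValueError):
            melting_temp("ACGTN" + "ACGT" * 4)
        with pytest.raises(ValueError):
            melting_temp("ACGTACG")


def flanked_msa(seed=73, members=("m1", "m2", "m3", "m4", "m5"),
                block_span=(500, 500), carrier_insert=0,
                events_extra=None):
    """A bait with a planted insertion block at position 500."""
    rng = np.random.default_rng(seed)
    bait = random_dna(rng, 1_000)
    events = {}
    for i, m in enumerate(members):
        ev = MemberEvents()
        if carrier_insert and i == 0:
            ev.insertions.append((500, "A" * carrier_insert))
        events[m] = ev
    if events_extra:
        for m, ev in events_extra.items():
            events[m] = ev
    return AnchoredMSA("bait", bait, list(members), events)


class TestConservedWindows:
    def test_identical_flanks_span_full_search_region(self):
        msa = flanked_msa(carrier_insert=40)
        b = IndelBlock(GenomicInterval("bait", 500, 500),
                       {m: 0 for m in msa.member_ids} | {"m1": 40,
                                                         REF_MEMBER: 0})
        left, right = conserved_flank_windows(msa, b)
        # insertion junction poisons columns 499/500 only
        assert left == [(250, 499)]
        assert right == [(501, 750)]

    def test_snp_column_excluded(self):
        extra = {"m2": MemberEvents(substitutions=[(400, "T")])}
        msa = flanked_msa(events_extra=extra, carrier_insert=40)
        b = IndelBlock(GenomicInterval("bait", 500, 500), {"m1": 40,
                                                           REF_MEMBER: 0})
        left, _ = conserved_flank_windows(msa, b)
        assert all(not (s <= 400 < e) for s, e in left)

    def test_member_gap_excludes_span(self):
        extra = {"m2": MemberEvents(deletions=[(600, 605)])}
        msa = flanked_msa(events_extra=extra, carrier_insert=40)
        b = IndelBlock(GenomicInterval("bait", 500, 500), {"m1": 40,
                                                           REF_MEMBER: 0})
        _, right = conserved_flank_windows(msa, b)
        for s, e in right:
            assert e <= 600 or s >= 605


class TestDesign:
    def test_clean_flanks_give_pair_with_exact_product_difference(self):
        msa = flanked_msa(carrier_insert=40)
        b = IndelBlock(GenomicInterval("bait", 500, 500),
                       {"m1": 40, "m2": 0, "m3": 0, "m4": 0, "m5": 0,
                        REF_MEMBER: 0})
        pair = design_primer_pair(msa, b, CFG)
        assert isinstance(pair, PrimerPair)
        prods = pair.product_len_by_member
        assert prods["m1"] - prods[REF_MEMBER] == 40
        assert prods["m2"] == prods[REF_MEMBER]
        for p in prods.values():
            assert CFG.product_min <= p <= CFG.product_max
        assert CFG.primer_len_min <= len(pair.forward_seq) \
            <= CFG.primer_len_max
        assert abs(pair.tm_forward_c - pair.tm_reverse_c) <= 3.0
        for tm in (pair.tm_forward_c, pair.tm_reverse_c):
            assert CFG.primer_tm_min_c <= tm <= CFG.primer_tm_max_c
        # primer sites never overlap the block
        assert pair.forward_ref_interval.end <= 500
        assert pair.reverse_ref_interval.start >= 500

    def test_oversized_carrier_allele_fails_product_bounds(self):
        msa = flanked_msa(carrier_insert=480)
        b = IndelBlock(GenomicInterval("bait", 500, 500),
                       {"m1": 480, "m2": 0, "m3": 0, "m4": 0, "m5": 0,
                        REF_MEMBER: 0})
        res = design_primer_pair(msa, b, CFG)
        assert isinstance(res, DesignFailure)
        assert res.reason == "product_bounds"

    def test_fully_polymorphic_flanks_fail_no_conserved_flank(self):
        subs = {f"m{i}": MemberEvents(
            substitutions=[(p, "A") for p in range(0, 1_000)])
            for i in range(1, 6)}
        msa = flanked_msa(events_extra=subs)
        b = IndelBlock(GenomicInterval("bait", 500, 500),
                       {"m1": 40, REF_MEMBER: 0})
        res = design_primer_pair(msa, b, CFG)
        assert isinstance(res, DesignFailure)
        assert res.reason == "no_conserved_flank"

    def test_tiny_flank_fails_no_feasible_primer(self):
        # conserved windows exist but are shorter than any primer
        extra = {"m2": MemberEvents(
            substitutions=[(p, "A") for p in range(250, 1_000, 10)
                           if not 495 <= p <= 505])}
        msa = flanked_msa(events_extra=extra)
        b = IndelBlock(GenomicInterval("bait", 500, 500),
                       {"m1": 40, REF_MEMBER: 0})
        res = design_primer_pair(msa, b, CFG)
        assert isinstance(res, DesignFailure)
        assert res.reason == "no_feasible_primer"


class TestUniqueness:
    def _pair(self, fwd, rev):
        return PrimerPair(fwd, rev,
                          GenomicInterval("c", 0, len(fwd)),
                          GenomicInterval("c", 0, len(rev), "-"),
                          60.0, 60.0, {})

    def test_count_occurrences_allows_overlap(self):
        assert count_occurrences("AA", "AAAA") == 3

    def test_planted_once_is_unique(self):
        rng = np.random.default_rng(74)
        seq = random_dna(rng, 50_000)
        fwd, rev_site = seq[1_000:1_020], seq[1_300:1_320]
        ref = GenomeAssembly("r", chromosomes={"c": seq})
        assert uniqueness_check(self._pair(fwd, revcomp(rev_site)),
                                ref) == "unique"

    def test_minus_strand_copy_makes_multi(self):
        rng = np.random.default_rng(75)
        seq = random_dna(rng, 20_000)
        fwd = seq[1_000:1_020]
        seq2 = seq + revcomp(fwd) + random_dna(rng, 500)
        ref = GenomeAssembly("r", chromosomes={"c": seq2})
        rev_site = seq[1_300:1_320]
        assert uniqueness_check(self._pair(fwd, revcomp(rev_site)),
                                ref) == "multi"

    def test_mutated_copy_does_not_count(self):
        rng = np.random.default_rng(76)
        seq = random_dna(rng, 20_000)
        fwd = seq[1_000:1_020]
        mutated = "T" + fwd[1:] if fwd[0] != "T" else "A" + fwd[1:]
        ref = GenomeAssembly(
            "r", chromosomes={"c": seq + mutated + random_dna(rng, 100)})
        rev_site = seq[1_300:1_320]
        assert uniqueness_check(self._pair(fwd, revcomp(rev_site)),
                                ref) == "unique"
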