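import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from indelmark.config import PipelineConfig
from indelmark.insilico_pcr import (find_binding_sites, genotype_accession,
                                    genotype_panel, merge_bands,
                                    predict_amplicons)
from indelmark.indel_screen import DiagnosticCall, IndelBlock
from indelmark.primer_design import Marker, PrimerPair
from indelmark.seq_io import GenomeAssembly, GenomicInterval, revcomp
from conftest import random_dna
from oracles import scan_binding_sites

CFG = PipelineConfig()


def make_marker(fwd, rev, name="M1", chrom="c"):
    pair = PrimerPair(fwd, rev,
                      GenomicInterval(chrom, 0, len(fwd)),
                      GenomicInterval(chrom, 0, len(rev), "-"),
                      60.0, 60.0, {})
    b = IndelBlock(GenomicInterval(chrom, 0, 1), {"REF": 1})
    return Marker(name, chrom, 0, pair, b,
                  DiagnosticCall("full", {0}, set(), 40),
                  GenomicInterval(chrom, 0, 1))


class TestBindingSites:
    def test_exact_planted_site_found(self):
        rng = np.random.default_rng(81)
        seq = random_dna(rng, 5_000)
        primer = seq[1_200:1_220]
        assert (1_200, "+") in find_binding_sites(primer, seq)

    def test_three_prime_terminal_mismatch_rejected(self):
        rng = np.random.default_rng(82)
        seq = random_dna(rng, 2_000)
        site = seq[700:720]
        primer = site[:-1] + ("A" if site[-1] != "A" else "C")
        sites = find_binding_sites(primer, seq)
        assert (700, "+") not in sites

    def test_internal_mismatches_tolerated_up_to_limit(self):
        rng = np.random.default_rng(83)
        seq = random_dna(rng, 2_000)
        site = list(seq[700:720])
        for p in (3, 8):
            site[p] = "A" if site[p] != "A" else "C"
        assert (700, "+") in find_binding_sites("".join(site), seq)
        site[12] = "A" if site[12] != "A" else "C"  # third mismatch
        assert (700, "+") not in find_binding_sites("".join(site), seq)

    def test_matches_position_by_position_scan_on_random_sequences(self):
        """Seed-and-verify search is identical to the brute-force scan on
        50 seeded 10-kb sequences."""
        for seed in range(50):
            rng = np.random.default_rng(2_000 + seed)
            seq = random_dna(rng, 10_000)
            # plant a near-copy to create mismatch sites
            primer = seq[4_000:4_020]
            noisy = list(primer)
            noisy[5] = "A" if noisy[5] != "A" else "C"
            seq = seq[:7_000] + "".join(noisy) + seq[7_020:]
            got = find_binding_sites(primer, seq, 2, 3)
            assert got == scan_binding_sites(primer, seq, 2, 3), \
                f"seed {seed}"


class TestAmplicons:
    def test_single_product(self):
        rng = np.random.default_rng(84)
        seq = random_dna(rng, 3_000)
        fwd = seq[1_000:1_020]
        rev = revcomp(seq[1_320:1_340])
        pair = make_marker(fwd, rev).primer_pair
        amps = predict_amplicons(pair, "c", seq, CFG)
        assert len(amps) == 1
        assert amps[0].length == 340

    def test_forward_site_only_gives_nothing(self):
        rng = np.random.default_rng(85)
        seq = random_dna(rng, 3_000)
        fwd = seq[1_000:1_020]
        rev = revcomp(random_dna(rng, 20))
        pair = make_marker(fwd, rev).primer_pair
        assert predict_amplicons(pair, "c", seq, CFG) == []

    def test_duplicated_locus_gives_two_amplicons(self):
        rng = np.random.default_rng(86)
        locus = random_dna(rng, 400)
        # copies far enough apart that no cross-copy product fits
        seq = random_dna(rng, 1_000) + locus + random_dna(rng, 2_500) + \
            locus + random_dna(rng, 500)
        fwd = locus[20:40]
        rev = revcomp(locus[320:340])
        pair = make_marker(fwd, rev).primer_pair
        amps = predict_amplicons(pair, "c", seq, CFG)
        assert len(amps) == 2
        assert amps[0].length == amps[1].length == 320


class TestGelModel:
    def test_merge_means_close_lengths(self):
        assert merge_bands([300, 308], 20) == [304.0]
        assert merge_bands([300, 340], 20) == [300.0, 340.0]

    @given(st.lists(st.integers(50, 2_000), min_size=0, max_size=12),
           st.permutations(range(12)))
    @settings(max_examples=60, deadline=None)
    def test_merge_idempotent_and_order_independent(self, lengths, perm):
        merged = merge_bands(lengths, 20)
        assert merge_bands(merged, 20) == merged
        shuffled = [lengths[i % len(lengths)] for i in perm] if lengths \
            else []
        assert merge_bands(lengths + shuffled, 20) == \
            merge_bands(shuffled + lengths, 20)


class TestGenotype:
    def _het_assembly(self, indel=40, seed=87):
        rng = np.random.default_rng(seed)
        hap1 = random_dna(rng, 3_000)
        # haplotype 2 carries a deletion inside the amplicon
        hap2 = hap1[:1_150] + hap1[1_150 + indel:]
        return GenomeAssembly("acc", "sp", "wild", {"c": hap1},
                              haplotype2={"c": hap2}), hap1

    def test_homozygous_single_band(self):
        rng = np.random.default_rng(88)
        seq = random_dna(rng, 3_000)
        asm = GenomeAssembly("acc", "sp", "wild", {"c": seq})
        marker = make_marker(seq[1_000:1_020], revcomp(seq[1_320:1_340]))
        cell = genotype_accession(marker, asm, CFG)
        assert cell.status == "ok" and cell.band_lengths == [340.0]

    def test_heterozygous_indel_gives_two_bands(self):
        asm, hap1 = self._het_assembly(indel=40)
        marker = make_marker(hap1[1_000:1_020], revcomp(hap1[1_320:1_340]))
        cell = genotype_accession(marker, asm, CFG)
        assert cell.band_lengths == [300.0, 340.0]
        assert cell.two_band_cause == "heterozygous"

    def test_sub_resolution_heterozygosity_merges_to_one_band(self):
        asm, hap1 = self._het_assembly(indel=8)
        marker = make_marker(hap1[1_000:1_020], revcomp(hap1[1_320:1_340]))
        cell = genotype_accession(marker, asm, CFG)
        assert cell.band_lengths == [336.0]  # mean of 332 and 340
        assert cell.status == "ok"

    def test_no_amplification_status(self):
        rng = np.random.default_rng(89)
        seq = random_dna(rng, 2_000)
        marker = make_marker(random_dna(rng, 20), random_dna(rng, 20))
        asm = GenomeAssembly("acc", "sp", "wild", {"c": seq})
        assert genotype_accession(marker, asm, CFG).status == \
            "no_amplification"


def test_panel_genotyping_matches_per_cell_path(mini_panel, mini_result):
    """The pooled-seed batch genotyper returns exactly the band sets of
    the per-accession scan."""
    markers = mini_result.markers
    assert markers
    assemblies = [mini_panel.reference] + mini_panel.others
    cells = genotype_panel(markers, assemblies, mini_result.config)
    for marker in markers:
        for asm in assemblies:
            a = cells[(marker.name, asm.accession_id)]
            b = genotype_accession(marker, asm, mini_result.config)
            assert a.band_lengths == b.band_lengths
            assert a.status == b.status


def test_reference_epcr_reproduces_designed_product(mini_panel,
                                                    mini_result):
    """Every designed marker amplifies exactly one reference band whose
    length equals the designed reference product."""
    for marker in mini_result.markers:
        cell = genotype_accession(marker, mini_panel.reference,
                                  mini_result.config)
        assert cell.status == "ok"
        assert len(cell.band_lengths) == 1
        assert cell.band_lengths[0] == pytest.approx(
            marker.primer_pair.product_len_by_member["REF"])
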