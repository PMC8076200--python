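import numpy as np
import pytest

from indelmark.anchored_alignment import (BandOverflowError,
                                          banded_global_align,
                                          align_with_anchors, deproject,
                                          project_to_msa)
from indelmark.bait_selection import BaitRegion
from indelmark.config import PipelineConfig
from indelmark.ortholog_extraction import find_orthologous_region
from indelmark.seq_io import GenomeAssembly, GenomicInterval
from conftest import random_dna
from oracles import affine_global_score


class TestBandedAligner:
    def test_identical_sequences(self):
        rng = np.random.default_rng(41)
        s = random_dna(rng, 1_000)
        aln = banded_global_align(s, s, band_width=50)
        assert aln.score == pytest.approx(1_000.0)
        assert aln.identity == 1.0
        assert "-" not in aln.aligned_bait + aln.aligned_query

    def test_contiguous_deletion_is_one_gap_run(self):
        rng = np.random.default_rng(42)
        s = random_dna(rng, 600)
        q = s[:300] + s[330:]  # 30-bp deletion
        aln = banded_global_align(s, q, band_width=100)
        runs = [r for r in aln.aligned_query.split(
            aln.aligned_query.strip("-")) if r]  # crude edge check
        gap_runs = [g for g in
                    "".join("G" if c == "-" else "." for c in
                            aln.aligned_query).split(".") if g]
        assert gap_runs == ["G" * 30]
        assert "-" not in aln.aligned_bait
        assert aln.score == pytest.approx(
            affine_global_score(s, q), abs=1e-6)

    def test_banded_equals_unbanded_bruteforce_on_random_pairs(self):
        """With the default band width the banded DP reproduces the
        optimal unbanded score on 50 seeded random pairs up to 500 bp."""
        for seed in range(50):
            rng = np.random.default_rng(1_000 + seed)
            n, m = rng.integers(30, 501, 2)
            a, b = random_dna(rng, int(n)), random_dna(rng, int(m))
            # mix of unrelated and mutated pairs
            if seed % 2:
                b = _mutate(a, rng)
            aln = banded_global_align(a, b, band_width=500)
            assert aln.score == pytest.approx(
                affine_global_score(a, b), abs=1e-6), f"seed {seed}"
            assert aln.aligned_bait.replace("-", "") == a
            assert aln.aligned_query.replace("-", "") == b

    def test_automatic_band_widening_recovers_optimum(self):
        # a 1-bp frame shift needs |d|=1, the edge of a width-1 band:
        # the doubling retry must still deliver the exact optimum
        rng = np.random.default_rng(77)
        a = random_dna(rng, 200)
        b = a[1:] + "A"
        aln = banded_global_align(a, b, band_width=1)
        assert aln.score == pytest.approx(affine_global_score(a, b),
                                          abs=1e-6)

    def test_band_overflow_raises_after_doubling(self):
        # block transposition forces the optimal path 40 diagonals off
        # center; width 2 (even quadrupled) cannot contain it
        rng = np.random.default_rng(12)
        block = random_dna(rng, 40)
        core = random_dna(rng, 200)
        a = block + core
        b = core + random_dna(rng, 40)
        with pytest.raises(BandOverflowError):
            banded_global_align(a, b, band_width=2)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            banded_global_align("", "ACGT")


def _mutate(s, rng):
    out = list(s)
    for _ in range(int(rng.integers(1, 6))):
        p = int(rng.integers(0, len(out)))
        out[p] = "ACGT"[int(rng.integers(0, 4))]
    if rng.random() < 0.5 and len(out) > 60:
        p = int(rng.integers(0, len(out) - 40))
        del out[p:p + int(rng.integers(5, 40))]
    return "".join(out)


def _aligned_pair(bait_seq, derived_seq, cfg):
    """Align a derived sequence to a bait through the anchor machinery."""
    bait = BaitRegion(GenomicInterval("c", 0, len(bait_seq)), bait_seq, 0.0)
    genome = GenomeAssembly("der", "x", "wild", {"c": derived_seq})
    hit = find_orthologous_region(bait, genome, cfg)
    assert hit is not None
    return align_with_anchors(bait_seq, hit.sequence, hit.anchors_bait,
                              hit.anchors_seq, cfg.anchor_kmer,
                              query_id="der")


class TestProjection:
    CFG = PipelineConfig()

    def test_identical_member_has_no_events(self):
        rng = np.random.default_rng(51)
        s = random_dna(rng, 20_000)
        aln = _aligned_pair(s, s, self.CFG)
        msa = project_to_msa("bait", s, [aln])
        ev = msa.events["der"]
        assert not ev.deletions and not ev.insertions \
            and not ev.substitutions
        assert msa.n_columns == len(s)

    def test_planted_events_recovered_at_positions(self):
        rng = np.random.default_rng(52)
        s = random_dna(rng, 20_000)
        # 40-bp deletion at 5,000 and a 25-bp insertion at 7,000
        ins = random_dna(rng, 25)
        derived = s[:5_000] + s[5_040:7_000] + ins + s[7_000:]
        aln = _aligned_pair(s, derived, self.CFG)
        msa = project_to_msa("bait", s, [aln])
        ev = msa.events["der"]
        dels = [d for d in ev.deletions if d[1] - d[0] >= 20]
        inss = [i for i in ev.insertions if len(i[1]) >= 20]
        assert len(dels) == 1 and len(inss) == 1
        ds, de = dels[0]
        assert de - ds == 40 and abs(ds - 5_000) <= 40  # left-aligned
        ip, iseq = inss[0]
        assert len(iseq) == 25 and abs(ip - 7_000) <= 25

    def test_deprojection_reproduces_members(self):
        from indelmark.simgen import MutationModel, evolve_genome

        rng = np.random.default_rng(53)
        s = random_dna(rng, 15_000)
        model = MutationModel(snp_rate=0.01, small_indel_rate=5e-4,
                              large_indel_rate=2e-4)
        for seed in range(3):
            chroms, _ = evolve_genome({"c": s}, model,
                                      np.random.default_rng(seed))
            aln = _aligned_pair(s, chroms["c"], self.CFG)
            msa = project_to_msa("bait", s, [aln])
            assert deproject(msa, "der") == aln.query_seq
            # member length arithmetic
            assert msa.member_length("der") == len(aln.query_seq)

    def test_bait_row_mismatch_rejected(self):
        rng = np.random.default_rng(54)
        s = random_dna(rng, 500)
        aln = banded_global_align(s, s, band_width=20)
        with pytest.raises(ValueError, match="degapped"):
            project_to_msa("bait", s[:-1] + "A" if s[-1] != "A"
                           else s[:-1] + "C", [aln])

    def test_aligned_fasta_emission_round_trips(self, tmp_path):
        from indelmark.anchored_alignment import msa_to_fasta

        rng = np.random.default_rng(58)
        s = random_dna(rng, 3_000)
        derived = s[:1_000] + s[1_030:2_000] + "ACGTA" * 5 + s[2_000:]
        aln = _aligned_pair(s, derived, self.CFG)
        msa = project_to_msa("bait", s, [aln])
        out = tmp_path / "aln.fa"
        msa_to_fasta(msa, out)
        lines = out.read_text().splitlines()
        rows = {lines[i][1:]: lines[i + 1]
                for i in range(0, len(lines), 2)}
        assert rows["bait"].replace("-", "") == s
        assert rows["der"].replace("-", "") == derived
        assert len(set(len(r) for r in rows.values())) == 1

    def test_events_are_left_aligned(self):
        # deletion inside a homopolymer must shift to the run start
        s = "ACGTAC" + "T" * 10 + "GCGTACGTAGCATCAGCATCAG" * 40
        q = s[:8] + s[11:]  # delete 3 T's mid-run
        aln = banded_global_align(s, q, band_width=30)
        msa = project_to_msa("bait", s, [aln])
        (ds, de), = msa.events["der" if "der" in msa.events else
                              aln.query_id].deletions
        assert ds == 6  # start of the homopolymer run
        assert de - ds == 3
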