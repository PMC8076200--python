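import numpy as np
import pytest

from indelmark.genotyping import (AccessionInfo, GenotypeMatrix,
                                  call_polymorphism, call_progeny_genotype,
                                  categorize_markers, detect_introgressions,
                                  interval_statistics,
                                  load_rice_validation_counts,
                                  species_marker_sets,
                                  summarize_polymorphism, two_band_percent,
                                  validation_rate, wild_accession_counts)
from indelmark.insilico_pcr import BandSet


def cell(bands, status="ok", acc="a"):
    return BandSet(acc, [float(b) for b in bands], [], status)


class TestCallPolymorphism:
    def test_resolvable_size_difference_is_polymorphic(self):
        assert call_polymorphism(cell([340]), cell([300]), 20) == \
            "polymorphic"

    def test_sub_resolution_difference_is_monomorphic(self):
        assert call_polymorphism(cell([310]), cell([300]), 20) == \
            "monomorphic"

    def test_failed_reference_not_evaluable(self):
        assert call_polymorphism(
            cell([300]), cell([], "no_amplification"), 20) == \
            "not_evaluable"

    def test_band_count_difference_is_polymorphic(self):
        assert call_polymorphism(cell([300, 340]), cell([300]), 20) == \
            "polymorphic"


def toy_matrix(columns, refs=("R1",)):
    """columns: accession -> list of band sets per marker."""
    accs = [AccessionInfo(a, "sp", "cultivar_indica" if a in refs
                          else "wild") for a in columns]
    n = len(next(iter(columns.values())))
    markers = [f"M{i}" for i in range(n)]
    cells = {(m, a): columns[a][i]
             for i, m in enumerate(markers) for a in columns}
    return GenotypeMatrix(markers, accs, cells, list(refs))


class TestCategorize:
    def test_mixed_matrix_totals(self):
        # 10 markers x 3 accessions: 7 polymorphic, 2 monomorphic, 1
        # failing in half its cells (2 of 3 > 30%)
        ref, a, b = [], [], []
        for i in range(7):
            ref.append(cell([300]))
            a.append(cell([340]))
            b.append(cell([300]))
        for i in range(2):
            ref.append(cell([300]))
            a.append(cell([300]))
            b.append(cell([305]))
        ref.append(cell([300]))
        a.append(cell([], "no_amplification"))
        b.append(cell([], "excess_bands"))
        m = toy_matrix({"R1": ref, "acc1": a, "acc2": b})
        _, totals = categorize_markers(m)
        assert totals == {"polymorphic": 7, "monomorphic": 2, "failed": 1}

    def test_all_identical_matrix_is_all_monomorphic(self):
        m = toy_matrix({"R1": [cell([300])] * 4,
                        "acc1": [cell([300])] * 4})
        _, totals = categorize_markers(m)
        assert totals == {"polymorphic": 0, "monomorphic": 4, "failed": 0}

    def test_category_partition_on_random_matrices(self):
        rng = np.random.default_rng(91)
        for _ in range(10):
            n = int(rng.integers(3, 15))
            cols = {}
            for a in ("R1", "x", "y", "z"):
                col = []
                for _ in range(n):
                    r = rng.random()
                    if r < 0.15:
                        col.append(cell([], "no_amplification"))
                    else:
                        col.append(cell([int(rng.integers(100, 500))]))
                cols[a] = col
            _, totals = categorize_markers(toy_matrix(cols))
            assert sum(totals.values()) == n

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            categorize_markers(toy_matrix({"R1": []}))


class TestPublishedCounts:
    """Arithmetic over the published validation table of the 475-marker
    rice panel (21 wild/African accessions vs cultivar IR24)."""

    def test_mean_min_max_of_wild_counts(self):
        table = load_rice_validation_counts()
        counts = wild_accession_counts(table)
        assert len(counts) == 21
        stats = summarize_polymorphism(counts)
        assert stats["mean"] == 323.0
        assert stats["min"] == 187 and stats["min_accession"] == "Glum_A09"
        assert stats["max"] == 391 and stats["max_accession"] == "Long_A11"

    def test_validation_rate(self):
        assert validation_rate(541, 475) == 87.8
        assert validation_rate(10, 10) == 100.0
        assert validation_rate(10, 0) == 0.0
        with pytest.raises(ValueError):
            validation_rate(0, 0)

    @pytest.mark.parametrize("count,expected", [
        (60, 12.632), (44, 9.263), (18, 3.789), (1, 0.211), (0, 0.0)])
    def test_two_band_percentages(self, count, expected):
        assert two_band_percent(count, 475) == expected

    def test_table_percentages_self_consistent(self):
        table = load_rice_validation_counts()
        for _, row in table.iterrows():
            assert two_band_percent(int(row["two_band_count"]), 475) == \
                pytest.approx(row["two_band_percent"], abs=0.001)


class TestSpeciesSets:
    def test_hand_counted_membership_pattern(self):
        # 5 markers polymorphic in (3, 3, 2, 1, 0) of the 3 accessions
        patterns = [3, 3, 2, 1, 0]
        cols = {"R1": [cell([300])] * 5}
        for ai in range(3):
            cols[f"w{ai}"] = [cell([340] if p > ai else [300])
                              for p in patterns]
        m = toy_matrix(cols)
        sets = species_marker_sets(m, {"spA": ["w0", "w1", "w2"]}, "R1")
        s = sets["spA"]
        assert len(s.common3) == 2
        assert len(s.common2) == 1
        assert len(s.specific) == 1
        assert len(s.union) == 4
        assert len(s.common3) + len(s.common2) + len(s.specific) == \
            len(s.union)

    def test_duplicate_accession_columns_spread_nothing(self):
        col = [cell([340]), cell([300])]
        cols = {"R1": [cell([300])] * 2, "w0": col, "w1": list(col),
                "w2": list(col)}
        m = toy_matrix(cols)
        s = species_marker_sets(m, {"sp": ["w0", "w1", "w2"]}, "R1")["sp"]
        assert not s.common2 and not s.specific
        assert s.common3 == {"M0"}


class TestIntervals:
    def test_regular_spacing(self):
        stats = interval_statistics(
            {"chr1": [300_000, 1_300_000, 2_300_000]})
        assert stats["mean_gap_kb"] == 1_000.0
        assert [g[3] for g in stats["gaps"]] == [1_000_000, 1_000_000]
        assert stats["gaps_over_threshold"] == []

    def test_single_marker_contributes_no_gap(self):
        stats = interval_statistics({"chr1": [500], "chr2": [1, 3_000_001]})
        assert len(stats["gaps"]) == 1
        assert len(stats["gaps_over_threshold"]) == 1


class TestProgeny:
    def test_f1_shows_both_parental_bands(self):
        assert call_progeny_genotype([300], [340], [300, 340]) == "H"

    def test_single_parental_pattern(self):
        assert call_progeny_genotype([300], [340], [300]) == "A"
        assert call_progeny_genotype([300], [340], [340]) == "B"

    def test_unexpected_band_fails(self):
        assert call_progeny_genotype([300], [340], [420]) == "failed"

    def test_monomorphic_parents_not_evaluable(self):
        assert call_progeny_genotype([300], [305], [300]) == \
            "not_evaluable"


class TestIntrogressions:
    def test_single_internal_segment(self):
        calls = [("c1", p, f"m{i}", c) for i, (p, c) in enumerate(
            [(100, "A"), (200, "A"), (300, "H"), (400, "H"), (500, "A")])]
        (seg,) = detect_introgressions(calls)
        assert (seg.start_marker, seg.end_marker) == ("m2", "m3")
        assert seg.state == "H" and seg.n_markers == 2

    def test_four_isolated_loci_on_four_chromosomes(self):
        calls = []
        for c in range(4):
            calls += [(f"c{c}", 100, f"a{c}", "A"),
                      (f"c{c}", 200, f"h{c}", "H"),
                      (f"c{c}", 300, f"b{c}", "A")]
        segs = detect_introgressions(calls)
        assert len(segs) == 4
        assert all(s.n_markers == 1 for s in segs)

    def test_all_recurrent_calls_give_no_segment(self):
        calls = [("c1", p, f"m{p}", "A") for p in range(0, 500, 100)]
        assert detect_introgressions(calls) == []

    def test_failed_calls_are_transparent(self):
        calls = [("c1", 100, "m1", "H"), ("c1", 200, "m2", "failed"),
                 ("c1", 300, "m3", "H"), ("c1", 400, "m4", "A")]
        (seg,) = detect_introgressions(calls)
        assert (seg.start_marker, seg.end_marker) == ("m1", "m3")
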