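"""Genotype-matrix analytics: validation categories, polymorphism counts,
species-level marker sets, heterozygosity frequencies and progeny calls.

All band-pattern comparisons use the agarose gel model: two band sets are
distinguishable only when, after merging, some band lacks a counterpart
within the resolution threshold.  The bundled
``rice_aa_validation_counts.tsv`` table carries the published per-accession
polymorphic-marker and two-band counts for the 475-marker rice AA-genome
set (IR24 and Nipponbare as the two reference cultivars), used by the
summary operations as an analytics-only input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import pandas as pd

from .insilico_pcr import BandSet, merge_bands


@dataclass(frozen=True)
class AccessionInfo:
    accession_id: str
    species: str = ""
    group_label: str = "other"


@dataclass
class GenotypeMatrix:
    """Markers x accessions grid of band sets."""

    marker_names: list[str]
    accessions: list[AccessionInfo]
    cells: dict[tuple[str, str], BandSet]  # (marker, accession) -> bands
    reference_accessions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for m in self.marker_names:
            for a in self.accessions:
                if (m, a.accession_id) not in self.cells:
                    raise ValueError(
                        f"incomplete matrix: missing cell ({m}, "
                        f"{a.accession_id})")

    def cell(self, marker: str, accession: str) -> BandSet:
        return self.cells[(marker, accession)]

    @property
    def accession_ids(self) -> list[str]:
        return [a.accession_id for a in self.accessions]


@dataclass
class MarkerValidationRecord:
    category: str  # polymorphic | monomorphic | failed
    polymorphism_flags: dict[tuple[str, str], str]  # (accession, ref) -> flag
    two_band_accessions: set[str]


# ---------------------------------------------------------------------------
# band-set comparison
# ---------------------------------------------------------------------------

def bands_equivalent(a: Sequence[float], b: Sequence[float],
                     gel_resolution_bp: float) -> bool:
    """True when two band patterns are indistinguishable on the gel."""
    ma = merge_bands(list(a), gel_resolution_bp)
    mb = merge_bands(list(b), gel_resolution_bp)
    if len(ma) != len(mb):
        return False
    return all(abs(x - y) < gel_resolution_bp for x, y in zip(ma, mb))


def call_polymorphism(cell: BandSet, reference_cell: BandSet,
                      gel_resolution_bp: float) -> str:
    """``polymorphic`` / ``monomorphic`` / ``not_evaluable``."""
    if not cell.is_ok or not reference_cell.is_ok:
        return "not_evaluable"
    same = bands_equivalent(cell.band_lengths, reference_cell.band_lengths,
                            gel_resolution_bp)
    return "monomorphic" if same else "polymorphic"


# ---------------------------------------------------------------------------
# validation categories
# ---------------------------------------------------------------------------

def categorize_markers(matrix: GenotypeMatrix, gel_resolution_bp: float = 20,
                       failure_fraction: float = 0.3
                       ) -> tuple[dict[str, MarkerValidationRecord],
                                  dict[str, int]]:
    """Per-marker validation category plus the category totals.

    ``failed``: more than ``failure_fraction`` of cells show no/extra
    amplification; otherwise ``polymorphic`` if any accession differs from
    either reference cultivar; else ``monomorphic``.
    """
    if not matrix.marker_names:
        raise ValueError("empty matrix")
    refs = matrix.reference_accessions or matrix.accession_ids[:1]
    records: dict[str, MarkerValidationRecord] = {}
    totals = {"polymorphic": 0, "monomorphic": 0, "failed": 0}
    for m in matrix.marker_names:
        cells = [matrix.cell(m, a) for a in matrix.accession_ids]
        bad = sum(1 for c in cells if not c.is_ok)
        flags: dict[tuple[str, str], str] = {}
        two_band = {c.accession_id for c in cells if c.is_ok and
                    c.n_bands >= 2}
        if bad > failure_fraction * len(cells):
            cat = "failed"
        else:
            any_poly = False
            for a in matrix.accession_ids:
                for r in refs:
                    if a == r:
                        continue
                    flag = call_polymorphism(matrix.cell(m, a),
                                             matrix.cell(m, r),
                                             gel_resolution_bp)
                    flags[(a, r)] = flag
                    any_poly = any_poly or flag == "polymorphic"
            cat = "polymorphic" if any_poly else "monomorphic"
        totals[cat] += 1
        records[m] = MarkerValidationRecord(cat, flags, two_band)
    return records, totals


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def polymorphic_counts(matrix: GenotypeMatrix, reference: str,
                       gel_resolution_bp: float = 20,
                       validated_only: Optional[set[str]] = None
                       ) -> dict[str, int]:
    """Number of polymorphic markers between each accession and one
    reference cultivar."""
    markers = [m for m in matrix.marker_names
               if validated_only is None or m in validated_only]
    out: dict[str, int] = {}
    for a in matrix.accession_ids:
        if a == reference:
            continue
        out[a] = sum(
            1 for m in markers
            if call_polymorphism(matrix.cell(m, a),
                                 matrix.cell(m, reference),
                                 gel_resolution_bp) == "polymorphic")
    return out


def summarize_polymorphism(counts: Mapping[str, int]) -> dict:
    """Mean (1 decimal), min and max with their accessions."""
    if not counts:
        raise ValueError("no accessions")
    items = sorted(counts.items())
    values = [v for _, v in items]
    amin = min(items, key=lambda kv: (kv[1], kv[0]))
    amax = max(items, key=lambda kv: (kv[1], kv[0]))
    return {
        "count_per_accession": dict(items),
        "mean": round(sum(values) / len(values), 1),
        "min": amin[1],
        "min_accession": amin[0],
        "max": amax[1],
        "max_accession": amax[0],
    }


def validation_rate(n_designed: int, n_validated: int) -> float:
    """Percentage of designed markers that validated, to 1 decimal."""
    if n_designed <= 0:
        raise ValueError("n_designed must be positive")
    if not 0 <= n_validated <= n_designed:
        raise ValueError("n_validated outside [0, n_designed]")
    return round(100.0 * n_validated / n_designed, 1)


def two_band_frequency(matrix: GenotypeMatrix, accession: str,
                       n_validated: int,
                       validated_only: Optional[set[str]] = None
                       ) -> dict:
    """Count and percentage (3 decimals) of validated markers showing two
    or more resolvable bands in one accession."""
    if n_validated <= 0:
        raise ValueError("n_validated must be positive")
    if accession not in matrix.accession_ids:
        raise ValueError(f"unknown accession {accession!r}")
    count = 0
    for m in matrix.marker_names:
        if validated_only is not None and m not in validated_only:
            continue
        cell = matrix.cell(m, accession)
        if cell.is_ok and cell.n_bands >= 2:
            count += 1
    return {"count": count,
            "percent": two_band_percent(count, n_validated)}


def two_band_percent(count: int, n_validated: int) -> float:
    if n_validated <= 0:
        raise ValueError("n_validated must be positive")
    return round(100.0 * count / n_validated, 3)


# ---------------------------------------------------------------------------
# species-level marker sets
# ---------------------------------------------------------------------------

@dataclass
class SpeciesMarkerSets:
    species: str
    common3: set[str]
    common2: set[str]
    specific: set[str]

    @property
    def union(self) -> set[str]:
        return self.common3 | self.common2 | self.specific


def species_marker_sets(matrix: GenotypeMatrix,
                        species_to_accessions: Mapping[str, Sequence[str]],
                        reference: str, gel_resolution_bp: float = 20,
                        validated_only: Optional[set[str]] = None
                        ) -> dict[str, SpeciesMarkerSets]:
    """Per species: markers polymorphic vs the reference in all three,
    exactly two, or exactly one of its accessions."""
    out: dict[str, SpeciesMarkerSets] = {}
    for species, accs in species_to_accessions.items():
        if not accs:
            raise ValueError(f"species {species!r} has no accessions")
        c3, c2, sp = set(), set(), set()
        for m in matrix.marker_names:
            if validated_only is not None and m not in validated_only:
                continue
            n = sum(1 for a in accs if call_polymorphism(
                matrix.cell(m, a), matrix.cell(m, reference),
                gel_resolution_bp) == "polymorphic")
            if n >= 3:
                c3.add(m)
            elif n == 2:
                c2.add(m)
            elif n == 1:
                sp.add(m)
        out[species] = SpeciesMarkerSets(species, c3, c2, sp)
    return out


# ---------------------------------------------------------------------------
# distribution
# ---------------------------------------------------------------------------

def interval_statistics(positions_by_chrom: Mapping[str, Sequence[int]],
                        threshold_bp: int = 2_000_000) -> dict:
    """Neighboring-marker gaps per chromosome; mean gap in kb and the
    list of gaps exceeding the threshold."""
    gaps: list[tuple[str, int, int, int]] = []  # chrom, pos_a, pos_b, gap
    for chrom, positions in positions_by_chrom.items():
        ps = sorted(positions)
        for a, b in zip(ps, ps[1:]):
            gaps.append((chrom, a, b, b - a))
    mean_kb = round(sum(g[3] for g in gaps) / len(gaps) / 1000.0, 1) \
        if gaps else float("nan")
    return {
        "gaps": gaps,
        "mean_gap_kb": mean_kb,
        "gaps_over_threshold": [g for g in gaps if g[3] > threshold_bp],
    }


# ---------------------------------------------------------------------------
# progeny genotyping
# ---------------------------------------------------------------------------

def call_progeny_genotype(bands_parent_a: Sequence[float],
                          bands_parent_b: Sequence[float],
                          bands_progeny: Sequence[float],
                          gel_resolution_bp: float = 20) -> str:
    """``H`` when progeny shows both parental patterns, ``A``/``B`` when
    exactly one, ``failed`` otherwise; ``not_evaluable`` when the parents
    are indistinguishable."""
    if bands_equivalent(bands_parent_a, bands_parent_b, gel_resolution_bp):
        return "not_evaluable"
    union = list(bands_parent_a) + list(bands_parent_b)
    if bands_equivalent(bands_progeny, union, gel_resolution_bp):
        return "H"
    if bands_equivalent(bands_progeny, bands_parent_a, gel_resolution_bp):
        return "A"
    if bands_equivalent(bands_progeny, bands_parent_b, gel_resolution_bp):
        return "B"
    return "failed"


@dataclass(frozen=True)
class IntrogressionSegment:
    chrom: str
    start_marker: str
    end_marker: str
    start_pos: int
    end_pos: int
    state: str  # H or B
    n_markers: int


def detect_introgressions(calls: Sequence[tuple[str, int, str, str]]
                          ) -> list[IntrogressionSegment]:
    """Maximal runs of consecutive non-recurrent (H/B) calls.

    ``calls`` are (chrom, position, marker_name, call) ordered by position
    within each chromosome.  ``failed``/``not_evaluable`` calls are
    non-informative and neither extend nor break a run.
    """
    segments: list[IntrogressionSegment] = []
    by_chrom: dict[str, list[tuple[int, str, str]]] = {}
    for chrom, pos, name, call in calls:
        by_chrom.setdefault(chrom, []).append((pos, name, call))
    for chrom, items in by_chrom.items():
        items.sort()
        run: list[tuple[int, str, str]] = []
        for pos, name, call in items:
            if call in ("failed", "not_evaluable"):
                continue
            if call in ("H", "B"):
                run.append((pos, name, call))
            else:  # recurrent-parent call ends the run
                if run:
                    segments.append(_segment(chrom, run))
                    run = []
        if run:
            segments.append(_segment(chrom, run))
    segments.sort(key=lambda s: (s.chrom, s.start_pos))
    return segments


def _segment(chrom: str, run: list[tuple[int, str, str]]
             ) -> IntrogressionSegment:
    states = {c for _, _, c in run}
    return IntrogressionSegment(
        chrom=chrom,
        start_marker=run[0][1],
        end_marker=run[-1][1],
        start_pos=run[0][0],
        end_pos=run[-1][0],
        state="B" if states == {"B"} else "H",
        n_markers=len(run),
    )


# ---------------------------------------------------------------------------
# bundled validation counts
# ---------------------------------------------------------------------------

def load_rice_validation_counts() -> pd.DataFrame:
    """Published per-accession validation counts for the 475-marker rice
    AA-genome set (two reference cultivars: IR24 and Nipponbare)."""
    with resources.files("indelmark").joinpath(
            "data/rice_aa_validation_counts.tsv").open() as handle:
        return pd.read_csv(handle, sep="\t")


def wild_accession_counts(table: pd.DataFrame,
                          reference_column: str = "polymorphic_vs_IR24"
                          ) -> dict[str, int]:
    """Counts versus one reference for the 21 non-japonica accessions."""
    rows = table[~table["species"].str.contains("japonica")]
    return dict(zip(rows["sample"], rows[reference_column]))
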