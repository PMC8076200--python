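"""Truth-based scoring of pipeline output on simulated panels.

Couples the generator's ground truth (planted diagnostic InDels, known
heterozygosity, recombination segments) with pipeline results: planted
-event recovery, product-size compliance, heterozygosity ranking, and
progeny genotyping against known donor segments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .config import PipelineConfig
from .genotyping import call_progeny_genotype, detect_introgressions
from .insilico_pcr import genotype_panel
from .pipeline import PipelineResult
from .primer_design import Marker
from .seq_io import GenomeAssembly
from .simgen import Panel, Progeny


@dataclass
class RecoveryReport:
    n_eligible: int
    n_recovered: int
    n_markers_designed: int
    n_products_in_range: int
    two_band_count: dict[str, int]      # accession -> two-band markers
    n_validated: int

    @property
    def recovery_percent(self) -> float:
        if self.n_eligible == 0:
            return float("nan")
        return 100.0 * self.n_recovered / self.n_eligible

    @property
    def products_in_range_percent(self) -> float:
        if self.n_markers_designed == 0:
            return float("nan")
        return 100.0 * self.n_products_in_range / self.n_markers_designed


def score_recovery(panel: Panel, result: PipelineResult,
                   window: int = 100) -> RecoveryReport:
    """Fraction of planted diagnostic InDels (non-repeat context) that
    became validated polymorphic markers, plus product compliance and
    per-accession two-band counts."""
    cfg = result.config
    validated = result.validated_markers
    markers_by_chrom: dict[str, list[Marker]] = {}
    for m in result.markers:
        if m.name in validated:
            markers_by_chrom.setdefault(m.chrom, []).append(m)
    eligible = [d for d in panel.truth.diagnostic_events
                if not d.in_repeat_context]
    recovered = 0
    for d in eligible:
        lo, hi = d.ref_pos - window, d.ref_pos + d.length + window
        hits = [m for m in markers_by_chrom.get(d.chrom, [])
                if lo <= m.position_bp <= hi]
        recovered += bool(hits)
    in_range = sum(
        1 for m in result.markers
        if all(cfg.product_min <= p <= cfg.product_max
               for p in m.primer_pair.product_len_by_member.values()))
    two_band: dict[str, int] = {}
    if result.matrix is not None:
        for acc in result.matrix.accession_ids:
            two_band[acc] = sum(
                1 for name in validated
                if result.matrix.cell(name, acc).is_ok
                and result.matrix.cell(name, acc).n_bands >= 2)
    return RecoveryReport(
        n_eligible=len(eligible),
        n_recovered=recovered,
        n_markers_designed=len(result.markers),
        n_products_in_range=in_range,
        two_band_count=two_band,
        n_validated=len(validated),
    )


def _hap1_view(assembly: GenomeAssembly) -> GenomeAssembly:
    """The parent as transmitted to a gamete: haplotype 1 only."""
    if assembly.haplotype2 is None:
        return assembly
    return replace(assembly, haplotype2=None)


@dataclass
class ProgenyEvaluation:
    calls: list[tuple[str, int, str, str]]  # chrom, pos, marker, call
    informative: list[str]
    n_h_calls: int
    segments: list
    misassigned_markers: list[str]


def evaluate_progeny(markers: Sequence[Marker],
                     recurrent: GenomeAssembly, donor: GenomeAssembly,
                     progeny: Progeny, config: PipelineConfig
                     ) -> ProgenyEvaluation:
    """Genotype a progeny plant and compare marker calls to the truth
    donor segments.

    Parents are genotyped as transmitted (haplotype 1), which is what the
    cross simulator recombines.  Markers whose amplicon spans a
    recombination breakpoint are excluded from the exactness comparison
    (a chimeric product is genuinely ambiguous).
    """
    assemblies = [_hap1_view(recurrent), _hap1_view(donor),
                  progeny.assembly]
    cells = genotype_panel(list(markers), assemblies, config)
    rec_id, don_id = assemblies[0].accession_id, assemblies[1].accession_id
    prog_id = progeny.assembly.accession_id
    calls: list[tuple[str, int, str, str]] = []
    informative: list[str] = []
    misassigned: list[str] = []
    n_h = 0
    for m in markers:
        a = cells[(m.name, rec_id)]
        b = cells[(m.name, don_id)]
        p = cells[(m.name, prog_id)]
        if not (a.is_ok and b.is_ok and p.is_ok):
            call = "failed"
        else:
            call = call_progeny_genotype(a.band_lengths, b.band_lengths,
                                         p.band_lengths,
                                         config.gel_resolution_bp)
        if call == "not_evaluable":
            continue
        informative.append(m.name)
        calls.append((m.chrom, m.position_bp, m.name, call))
        if call == "H":
            n_h += 1
        # exact truth comparison, skipping breakpoint-spanning amplicons
        segs = progeny.donor_segments_ref.get(m.chrom, [])
        amp = m.amplicon
        on_breakpoint = any(
            (s - 1 <= amp.end and amp.start <= s + 1) or
            (e - 1 <= amp.end and amp.start <= e + 1)
            for s, e in segs)
        if on_breakpoint or call == "failed":
            continue
        in_donor = any(s <= m.position_bp < e for s, e in segs)
        if in_donor != (call in ("H", "B")):
            misassigned.append(m.name)
    segments = detect_introgressions(calls)
    return ProgenyEvaluation(calls=calls, informative=informative,
                             n_h_calls=n_h, segments=segments,
                             misassigned_markers=misassigned)


def truth_segments_with_markers(markers: Sequence[Marker],
                                progeny: Progeny,
                                names: Sequence[str] | None = None
                                ) -> list[tuple[str, int, int]]:
    """Truth donor segments containing at least one (informative)
    marker position."""
    keep = set(names) if names is not None else None
    out = []
    for chrom, segs in progeny.donor_segments_ref.items():
        pos = [m.position_bp for m in markers if m.chrom == chrom
               and (keep is None or m.name in keep)]
        for s, e in segs:
            if any(s <= p < e for p in pos):
                out.append((chrom, s, e))
    return out


def detected_truth_segments(segments, truth_segs) -> int:
    """How many truth segments overlap a detected segment."""
    n = 0
    for chrom, s, e in truth_segs:
        hit = any(seg.chrom == chrom and seg.start_pos < e and
                  seg.end_pos >= s for seg in segments)
        n += bool(hit)
    return n
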