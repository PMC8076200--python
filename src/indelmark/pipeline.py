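"""End-to-end marker development pipeline.

Stages: bait selection on the reference -> ortholog extraction from every
other genome -> reference-anchored alignment -> InDel screening and
diagnostic classification -> primer design with genome-wide uniqueness ->
in-silico PCR genotyping of the whole panel -> validation analytics.
Every stage is a pure function of (inputs, config); the pipeline never
draws random numbers.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .anchored_alignment import AnchoredMSA, align_to_bait, project_to_msa
from .bait_selection import BaitRegion, select_bait_windows, write_bait_table
from .config import PipelineConfig
from .genotyping import (AccessionInfo, GenotypeMatrix,
                         MarkerValidationRecord, categorize_markers,
                         interval_statistics, polymorphic_counts,
                         two_band_frequency, validation_rate)
from .indel_screen import (REF_MEMBER, classify_diagnostic,
                           extract_indel_blocks, select_markers_per_bait)
from .insilico_pcr import genotype_panel
from .kmer import KmerIndex
from .ortholog_extraction import (OrthologHit, OrthologRejection,
                                  OrthologSet, find_orthologs_batch,
                                  trim_to_bait)
from .primer_design import (DesignFailure, Marker, design_primer_pair,
                            flank_budget, name_marker, uniqueness_check)
from .seq_io import (GenomeAssembly, GenomicInterval, MarkerRecord,
                     write_bed, write_marker_table)

logger = logging.getLogger("indelmark")


@dataclass
class PipelineResult:
    config: PipelineConfig
    baits: list[BaitRegion]
    ortholog_sets: list[OrthologSet]
    rejections: list[OrthologRejection]
    msas: dict[str, AnchoredMSA]            # bait_id -> MSA
    markers: list[Marker]
    design_failures: dict[str, str]         # bait_id -> reason
    matrix: Optional[GenotypeMatrix]
    validation: dict[str, MarkerValidationRecord] = field(default_factory=dict)
    totals: dict[str, int] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    @property
    def validated_markers(self) -> set[str]:
        return {m for m, r in self.validation.items()
                if r.category == "polymorphic"}

    def marker_records(self) -> list[MarkerRecord]:
        return [m.to_record() for m in self.markers]


def run_pipeline(config: PipelineConfig, reference: GenomeAssembly,
                 genomes: list[GenomeAssembly],
                 outdir: Optional[str | Path] = None) -> PipelineResult:
    """Run every stage on one reference plus panel genomes."""
    if len(genomes) + 1 < config.min_ortholog_members:
        raise ValueError(
            f"need at least {config.min_ortholog_members} genomes "
            f"(reference included); got {len(genomes) + 1}")
    t0 = time.perf_counter()
    ref_index = KmerIndex(reference.chromosomes, config.repeat_kmer)
    baits = select_bait_windows(reference, config, ref_index)
    _stage("baits", t0, kept=len(baits))

    # genome-major hit collection: one anchor index per genome
    t0 = time.perf_counter()
    hits_by_bait: dict[str, dict[str, Optional[OrthologHit]]] = \
        {b.bait_id: {} for b in baits}
    for genome in genomes:
        batch = find_orthologs_batch(baits, genome, config)
        for bait in baits:
            hits_by_bait[bait.bait_id][genome.accession_id] = \
                batch[bait.bait_id]
    ortholog_sets: list[OrthologSet] = []
    rejections: list[OrthologRejection] = []
    for bait in baits:
        per_genome = hits_by_bait[bait.bait_id]
        hits = [h for h in per_genome.values() if h is not None]
        missing = {acc: "no co-linear anchor chain"
                   for acc, h in per_genome.items() if h is None}
        oset = OrthologSet(bait=bait, hits=hits, missing=missing)
        if oset.accepted(config.min_ortholog_members):
            ortholog_sets.append(oset)
        else:
            rejections.append(OrthologRejection(
                bait=bait, member_count=oset.member_count, missing=missing))
    _stage("orthologs", t0, sets=len(ortholog_sets),
           rejected=len(rejections))

    group_by_acc = {g.accession_id: g.group_label for g in genomes}
    group_by_acc[REF_MEMBER] = reference.group_label
    chrom_index = {c: i + 1 for i, c in
                   enumerate(reference.chromosomes)}

    t0 = time.perf_counter()
    msas: dict[str, AnchoredMSA] = {}
    markers: list[Marker] = []
    design_failures: dict[str, str] = {}
    n_blocks = 0
    for oset in ortholog_sets:
        bait = oset.bait
        alignments = []
        for hit in oset.hits:
            trimmed = trim_to_bait(hit, len(bait), config.anchor_kmer)
            aln = align_to_bait(
                bait.sequence, trimmed.sequence,
                anchors=(trimmed.anchors_bait, trimmed.anchors_seq),
                anchor_k=config.anchor_kmer,
                match=config.align_match, mismatch=config.align_mismatch,
                gap_open=config.align_gap_open,
                gap_extend=config.align_gap_extend,
                band_width=config.band_width,
                query_id=hit.source_accession)
            alignments.append(aln)
        msa = project_to_msa(bait.bait_id, bait.sequence, alignments,
                             missing=sorted(oset.missing))
        msas[bait.bait_id] = msa
        blocks = extract_indel_blocks(msa, config.min_gap_bp,
                                      config.merge_radius_bp)
        n_blocks += len(blocks)
        calls = [classify_diagnostic(b, group_by_acc, config.min_gap_bp)
                 for b in blocks]
        flanks = {i: flank_budget(msa, b, config.product_max // 2)
                  for i, b in enumerate(blocks)}
        selected = select_markers_per_bait(list(zip(blocks, calls)),
                                           config, flanks)
        if not selected:
            design_failures[bait.bait_id] = "no_diagnostic_block"
            continue
        mask = reference.mask_for(bait.interval.chrom)
        bait_mask = mask[bait.interval.start:bait.interval.end] \
            if mask is not None else None
        for block, call in selected:
            pair = design_primer_pair(msa, block, config, bait_mask)
            if isinstance(pair, DesignFailure):
                design_failures.setdefault(bait.bait_id, pair.reason)
                continue
            if uniqueness_check(pair, reference) != "unique":
                design_failures.setdefault(bait.bait_id, "primer_not_unique")
                continue
            chrom = bait.interval.chrom
            pos = bait.interval.start + block.ref_start
            name = name_marker(chrom_index[chrom], pos + 1)
            if any(m.name == name for m in markers):
                logger.warning("duplicate marker name %s dropped", name)
                continue
            amplicon = GenomicInterval(
                chrom,
                bait.interval.start + pair.forward_ref_interval.start,
                bait.interval.start + pair.reverse_ref_interval.end)
            markers.append(Marker(
                name=name, chrom=chrom, position_bp=pos,
                primer_pair=pair, block=block, diagnostic=call,
                amplicon=amplicon))
    markers.sort(key=lambda m: (chrom_index[m.chrom], m.position_bp))
    _stage("design", t0, blocks=n_blocks, markers=len(markers))

    # in-silico PCR genotyping of the whole panel
    t0 = time.perf_counter()
    accessions = [AccessionInfo(reference.accession_id, reference.species,
                                reference.group_label)]
    accessions += [AccessionInfo(g.accession_id, g.species, g.group_label)
                   for g in genomes]
    all_assemblies = [reference] + genomes
    matrix = None
    validation: dict[str, MarkerValidationRecord] = {}
    totals: dict[str, int] = {}
    summary: dict = {"n_baits": len(baits),
                     "n_ortholog_sets": len(ortholog_sets),
                     "n_rejected_sets": len(rejections),
                     "n_blocks": n_blocks,
                     "n_markers_designed": len(markers)}
    if markers:
        cells = genotype_panel(markers, all_assemblies, config)
        refs = [a.accession_id for a in accessions
                if a.group_label.startswith("cultivar")]
        matrix = GenotypeMatrix(
            marker_names=[m.name for m in markers],
            accessions=accessions,
            cells=cells,
            reference_accessions=refs or [reference.accession_id])
        validation, totals = categorize_markers(
            matrix, config.gel_resolution_bp,
            config.marker_failure_fraction)
        validated = {m for m, r in validation.items()
                     if r.category == "polymorphic"}
        summary["n_validated"] = len(validated)
        summary["validation_rate_percent"] = validation_rate(
            len(markers), len(validated)) if markers else 0.0
        positions: dict[str, list[int]] = {}
        for m in markers:
            if m.name in validated:
                positions.setdefault(m.chrom, []).append(m.position_bp)
        summary["interval_stats"] = interval_statistics(positions)
        if matrix.reference_accessions:
            ref0 = matrix.reference_accessions[0]
            counts = polymorphic_counts(matrix, ref0,
                                        config.gel_resolution_bp,
                                        validated)
            summary["polymorphic_counts_vs_" + ref0] = counts
        if validated:
            summary["two_band"] = {
                a.accession_id: two_band_frequency(
                    matrix, a.accession_id, len(validated), validated)
                for a in accessions}
    _stage("genotype", t0, cells=len(markers) * len(accessions),
           **{k: v for k, v in totals.items()})

    result = PipelineResult(
        config=config, baits=baits, ortholog_sets=ortholog_sets,
        rejections=rejections, msas=msas, markers=markers,
        design_failures=design_failures, matrix=matrix,
        validation=validation, totals=totals, summary=summary)
    if outdir is not None:
        write_outputs(result, Path(outdir))
    return result


def _stage(name: str, t0: float, **counts) -> None:
    extra = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s elapsed=%.1fs %s", name,
                time.perf_counter() - t0, extra)


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_bait_table(result.baits, outdir / "baits.tsv")
    records = result.marker_records()
    write_marker_table(records, outdir / "markers.tsv", allow_empty=True)
    write_bed(records, outdir / "markers.bed", allow_empty=True)
    if result.matrix is not None:
        write_matrix(result, outdir / "matrix.tsv")
    with open(outdir / "summary.tsv", "w") as out:
        out.write("key\tvalue\n")
        for key in ("n_baits", "n_ortholog_sets", "n_rejected_sets",
                    "n_blocks", "n_markers_designed", "n_validated",
                    "validation_rate_percent"):
            if key in result.summary:
                out.write(f"{key}\t{result.summary[key]}\n")


def write_matrix(result: PipelineResult, path: Path) -> None:
    """Markers x accessions TSV; cells are semicolon-joined band lengths
    plus the call status."""
    matrix = result.matrix
    with open(path, "w") as out:
        out.write("marker\t" + "\t".join(matrix.accession_ids) + "\n")
        for m in matrix.marker_names:
            row = [m]
            for a in matrix.accession_ids:
                cell = matrix.cell(m, a)
                bands = ";".join(f"{b:.0f}" for b in cell.band_lengths)
                row.append(f"{bands or '.'}|{cell.status}")
            out.write("\t".join(row) + "\n")


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter(
        "[%(asctime)s] %(name)s %(message)s", "%H:%M:%S"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
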