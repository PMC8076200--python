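"""InDel block extraction and diagnostic classification.

An InDel block groups the gap events of all members at one reference locus
(events whose reference spans fall within a 10-bp merge radius are one
block) and records each member's allele length there, the reference allele
length included.  A block is *diagnostic* when cultivar and wild allele
lengths separate by at least the gel-resolvable gap (>= 20 bp by default):
tier ``full`` when every cultivar/wild pair separates, ``partial`` when at
least one pair does, with members lacking an ortholog excluded from the
"all wild" quantifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .anchored_alignment import AnchoredMSA
from .config import PipelineConfig
from .seq_io import GenomicInterval

REF_MEMBER = "REF"


@dataclass
class IndelBlock:
    ref_interval: GenomicInterval  # bait-local coordinates, left-aligned
    allele_length_by_member: dict[str, int]

    @property
    def ref_start(self) -> int:
        return self.ref_interval.start

    @property
    def ref_end(self) -> int:
        return self.ref_interval.end

    @property
    def max_length_difference(self) -> int:
        vals = self.allele_length_by_member.values()
        return max(vals) - min(vals)


@dataclass
class DiagnosticCall:
    tier: str  # full | partial | none
    cultivar_lengths: set[int]
    discriminated_wild_members: set[str]
    gap_bp: int


def extract_indel_blocks(msa: AnchoredMSA, min_gap_bp: int,
                         merge_radius_bp: int = 10) -> list[IndelBlock]:
    """Convert member gap events into merged, length-filtered blocks."""
    raw: list[tuple[int, int, str, int]] = []  # (start, end, member, delta)
    for member in msa.member_ids:
        ev = msa.events[member]
        for s, e in ev.deletions:
            raw.append((s, e, member, -(e - s)))
        for p, seq in ev.insertions:
            raw.append((p, p, member, len(seq)))
    if not raw:
        return []
    raw.sort(key=lambda r: (r[0], r[1]))
    clusters: list[list[tuple[int, int, str, int]]] = []
    cur = [raw[0]]
    cur_end = raw[0][1]
    for r in raw[1:]:
        if r[0] <= cur_end + merge_radius_bp:
            cur.append(r)
            cur_end = max(cur_end, r[1])
        else:
            clusters.append(cur)
            cur = [r]
            cur_end = r[1]
    clusters.append(cur)

    blocks: list[IndelBlock] = []
    for cluster in clusters:
        s = min(r[0] for r in cluster)
        e = max(r[1] for r in cluster)
        ref_len = e - s
        alleles = {m: ref_len for m in msa.member_ids}
        alleles[REF_MEMBER] = ref_len
        for _, _, member, delta in cluster:
            alleles[member] += delta
        block = IndelBlock(
            ref_interval=GenomicInterval(msa.bait_id.split(":")[0]
                                         if ":" in msa.bait_id else "bait",
                                         s, e),
            allele_length_by_member=alleles,
        )
        if block.max_length_difference >= min_gap_bp:
            blocks.append(block)
    return blocks


def classify_diagnostic(block: IndelBlock,
                        group_label_by_member: Mapping[str, str],
                        min_gap_bp: int) -> DiagnosticCall:
    """Evaluate the cultivar-vs-wild separation quantifier for one block.

    Members absent from the block's allele map (missing orthologs) are
    excluded; an error is raised if no cultivar member remains.
    """
    cultivars: dict[str, int] = {}
    wild: dict[str, int] = {}
    for member, length in block.allele_length_by_member.items():
        label = group_label_by_member.get(member)
        if label is None:
            continue
        if label.startswith("cultivar"):
            cultivars[member] = length
        elif label == "wild":
            wild[member] = length
    if not cultivars:
        raise ValueError("diagnosis undefined: no cultivar member present")
    if not wild:
        return DiagnosticCall("none", set(cultivars.values()), set(), 0)
    qualifying: list[int] = []
    discriminated: set[str] = set()
    all_pairs_qualify = True
    for wm, wl in wild.items():
        member_all = True
        for cl in cultivars.values():
            diff = abs(cl - wl)
            if diff >= min_gap_bp:
                qualifying.append(diff)
            else:
                member_all = False
                all_pairs_qualify = False
        if member_all:
            discriminated.add(wm)
    if not qualifying:
        return DiagnosticCall("none", set(cultivars.values()), set(), 0)
    tier = "full" if all_pairs_qualify else "partial"
    return DiagnosticCall(tier, set(cultivars.values()), discriminated,
                          min(qualifying))


_TIER_RANK = {"full": 0, "partial": 1, "none": 2}


def select_markers_per_bait(
        blocks_with_calls: list[tuple[IndelBlock, DiagnosticCall]],
        config: PipelineConfig,
        flank_len: Optional[Mapping[int, int]] = None,
        ) -> list[tuple[IndelBlock, DiagnosticCall]]:
    """Pick at most ``max_markers_per_bait`` diagnostic blocks.

    Ranking: tier full > partial; larger minimum gap; longer available
    conserved flank (``flank_len`` maps block index -> bp, from the primer
    pre-scan); smaller reference start.  Selected blocks must be separated
    by at least ``product_max`` so their amplicons cannot overlap.
    """
    candidates = [(i, b, c) for i, (b, c) in enumerate(blocks_with_calls)
                  if c.tier != "none"]
    candidates.sort(key=lambda x: (
        _TIER_RANK[x[2].tier],
        -x[2].gap_bp,
        -(flank_len.get(x[0], 0) if flank_len else 0),
        x[1].ref_start,
    ))
    selected: list[tuple[IndelBlock, DiagnosticCall]] = []
    for _, block, call in candidates:
        if len(selected) >= config.max_markers_per_bait:
            break
        ok = all(_separation(block, other) >= config.product_max
                 for other, _ in selected)
        if ok:
            selected.append((block, call))
    selected.sort(key=lambda bc: bc[0].ref_start)
    return selected


def _separation(a: IndelBlock, b: IndelBlock) -> int:
    if a.ref_end <= b.ref_start:
        return b.ref_start - a.ref_end
    if b.ref_end <= a.ref_start:
        return a.ref_start - b.ref_end
    return 0


def write_block_table(blocks_with_calls, member_ids, path,
                      chrom: str = "", offset: int = 0) -> None:
    """TSV of blocks with per-member allele lengths (1-based positions)."""
    cols = ["chrom", "ref_start_1based", "ref_end_1based", "tier", "gap_bp",
            REF_MEMBER] + list(member_ids)
    with open(path, "w") as out:
        out.write("\t".join(cols) + "\n")
        for block, call in blocks_with_calls:
            row = [chrom or block.ref_interval.chrom,
                   str(offset + block.ref_start + 1),
                   str(offset + block.ref_end),
                   call.tier, str(call.gap_bp),
                   str(block.allele_length_by_member.get(REF_MEMBER, ""))]
            for m in member_ids:
                row.append(str(block.allele_length_by_member.get(m, "NA")))
            out.write("\t".join(row) + "\n")
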