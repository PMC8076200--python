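"""Orthologous-region extraction by unique k-mer anchoring and chaining.

For each bait the corresponding region of another genome is located from
seed matches between k-mers that are unique in BOTH the bait and the target
genome (k=15 by default), chained into the longest strictly co-linear run
on one chromosome and strand.  The chain span, padded by 2 kb and clipped
to the chromosome, is the ortholog hit; minus-strand hits are
reverse-complemented so all downstream coordinates are bait-forward.
Absence of a hit is a legal outcome (missing region or poor assembly).

Two equivalent entry points: :func:`find_orthologous_region` for one bait
against an indexed genome, and :func:`find_orthologs_batch`, which probes
one pass of the genome's k-mer stream against the pooled bait k-mers and
so avoids building a full per-genome index (used by the pipeline).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .bait_selection import BaitRegion
from .config import PipelineConfig
from .kmer import KmerIndex, encode, kmer_codes, rc_codes
from .seq_io import GenomeAssembly, GenomicInterval, revcomp

_MAX_CHAIN_ANCHORS = 4000  # stride-subsample denser anchor sets


@dataclass
class OrthologHit:
    source_accession: str
    interval: GenomicInterval  # on the source genome, + strand coords
    sequence: str              # bait-forward (revcomp'd for '-' hits)
    strand: str
    anchor_count: int
    anchor_span_fraction: float
    # anchor coordinates: bait position, position in `sequence`
    anchors_bait: np.ndarray = field(repr=False, default=None)
    anchors_seq: np.ndarray = field(repr=False, default=None)
    ambiguous: bool = False


@dataclass
class OrthologSet:
    bait: BaitRegion
    hits: list[OrthologHit]
    missing: dict[str, str] = field(default_factory=dict)

    @property
    def member_count(self) -> int:
        return len(self.hits) + 1  # the bait itself is a member

    def accepted(self, min_ortholog_members: int) -> bool:
        return self.member_count >= min_ortholog_members


@dataclass
class OrthologRejection:
    bait: BaitRegion
    member_count: int
    missing: dict[str, str]


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def _lis_chain(tpos: np.ndarray) -> np.ndarray:
    """Indices of the longest strictly increasing subsequence of ``tpos``
    (anchors pre-sorted by bait position; patience sorting)."""
    n = tpos.size
    tails: list[int] = []
    tails_idx: list[int] = []
    prev = np.full(n, -1, dtype=np.int64)
    tl = tpos.tolist()
    for i in range(n):
        v = tl[i]
        j = bisect_left(tails, v)
        if j == len(tails):
            tails.append(v)
            tails_idx.append(i)
        else:
            tails[j] = v
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    out = []
    i = tails_idx[-1] if tails_idx else -1
    while i >= 0:
        out.append(i)
        i = prev[i]
    return np.asarray(out[::-1], dtype=np.int64)


def _longest_gap_bounded(bpos: np.ndarray, tpos: np.ndarray,
                         max_gap: int) -> slice:
    """Longest contiguous chain piece whose adjacent anchors stay within
    ``max_gap`` in both coordinates."""
    if bpos.size == 0:
        return slice(0, 0)
    gaps = (np.diff(bpos) > max_gap) | (np.abs(np.diff(tpos)) > max_gap)
    best = (0, 0)
    start = 0
    for i, brk in enumerate(np.append(gaps, True)):
        if brk:
            if i + 1 - start > best[0]:
                best = (i + 1 - start, start)
            start = i + 1
    return slice(best[1], best[1] + best[0])


def _select_hit(bait: BaitRegion, genome: GenomeAssembly,
                groups: list[tuple[str, str, np.ndarray, np.ndarray]],
                config: PipelineConfig) -> Optional[OrthologHit]:
    """Pick the best co-linear chain among (strand, chrom, bpos, tpos)
    anchor groups and cut the padded hit."""
    k = config.anchor_kmer
    candidates = []
    for strand, chrom, bp, tp in groups:
        if bp.size == 0:
            continue
        order = np.argsort(bp, kind="stable")
        bp, tp = bp[order], tp[order]
        if bp.size > _MAX_CHAIN_ANCHORS:
            stride = int(np.ceil(bp.size / _MAX_CHAIN_ANCHORS))
            take = np.unique(np.append(np.arange(0, bp.size, stride),
                                       bp.size - 1))
            bp, tp = bp[take], tp[take]
        chain = _lis_chain(tp if strand == "+" else -tp)
        bp_c, tp_c = bp[chain], tp[chain]
        piece = _longest_gap_bounded(bp_c, tp_c, config.max_anchor_gap)
        bp_c, tp_c = bp_c[piece], tp_c[piece]
        if bp_c.size < config.min_anchors:
            continue
        span_frac = (bp_c[-1] + k - bp_c[0]) / len(bait)
        if span_frac < config.min_anchor_span_fraction:
            continue
        t_lo = int(min(tp_c[0], tp_c[-1]))
        t_hi = int(max(tp_c[0], tp_c[-1])) + k
        candidates.append((int(bp_c.size), t_hi - t_lo, chrom, t_lo,
                           strand, bp_c, tp_c, float(span_frac)))
    if not candidates:
        return None
    # most anchors; ties: smaller target interval, lexicographically
    # smallest chromosome, smallest start (determinism)
    candidates.sort(key=lambda x: (-x[0], x[1], x[2], x[3]))
    best = candidates[0]
    ambiguous = len(candidates) > 1 and candidates[1][0] >= 0.8 * best[0]
    count, _, chrom, t_lo, strand, bp_c, tp_c, span_frac = best
    L = len(genome.chromosomes[chrom])
    start = max(0, t_lo - config.ortholog_pad)
    end = min(L, int(max(tp_c)) + k + config.ortholog_pad)
    seq = genome.chromosomes[chrom][start:end]
    if strand == "-":
        seq = revcomp(seq)
        seq_pos = (end - start) - (tp_c - start) - k
    else:
        seq_pos = tp_c - start
    order = np.argsort(bp_c, kind="stable")
    return OrthologHit(
        source_accession=genome.accession_id,
        interval=GenomicInterval(chrom, start, end, strand),
        sequence=seq,
        strand=strand,
        anchor_count=count,
        anchor_span_fraction=span_frac,
        anchors_bait=bp_c[order].astype(np.int64),
        anchors_seq=seq_pos[order].astype(np.int64),
        ambiguous=ambiguous,
    )


def _bait_unique_kmers(bait: BaitRegion, k: int
                       ) -> tuple[np.ndarray, np.ndarray]:
    """(positions, codes) of k-mers occurring exactly once in the bait."""
    enc = encode(bait.sequence)
    codes, valid = kmer_codes(enc, k)
    if codes.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    _, inverse, counts = np.unique(codes, return_inverse=True,
                                   return_counts=True)
    sel = valid & (counts[inverse] == 1)
    idx = np.nonzero(sel)[0]
    return idx, codes[idx]


# ---------------------------------------------------------------------------
# single-bait and batch entry points
# ---------------------------------------------------------------------------

def find_orthologous_region(bait: BaitRegion, genome: GenomeAssembly,
                            config: PipelineConfig,
                            genome_index: Optional[KmerIndex] = None
                            ) -> Optional[OrthologHit]:
    """Best co-linear unique-anchor chain of the bait in ``genome``.

    Returns ``None`` when no chain reaches ``min_anchors`` anchors or
    spans at least half the bait.
    """
    k = config.anchor_kmer
    if genome_index is None:
        genome_index = KmerIndex(genome.chromosomes, k)
    bidx, fwd_codes = _bait_unique_kmers(bait, k)
    if bidx.size == 0:
        return None
    groups: list[tuple[str, str, np.ndarray, np.ndarray]] = []
    for strand, qcodes in (("+", fwd_codes),
                           ("-", rc_codes(fwd_codes, k))):
        qi, gpos = genome_index.locate_unique(qcodes)
        if qi.size == 0:
            continue
        ci, lpos = genome_index.split_global(gpos)
        for c in np.unique(ci):
            m = ci == c
            groups.append((strand, genome_index.chrom_names[int(c)],
                           bidx[qi[m]], lpos[m]))
    return _select_hit(bait, genome, groups, config)


def _within_run_offsets(reps: np.ndarray) -> np.ndarray:
    """Concatenated ``arange(r)`` for every r in ``reps``."""
    total = int(reps.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    out = np.ones(total, dtype=np.int64)
    out[0] = 0
    ends = np.cumsum(reps)[:-1]
    out[ends] = 1 - reps[:-1]
    return np.cumsum(out)


def find_orthologs_batch(baits: list[BaitRegion], genome: GenomeAssembly,
                         config: PipelineConfig
                         ) -> dict[str, Optional[OrthologHit]]:
    """Hits of every bait in one genome via a single k-mer stream pass.

    The pooled bait-unique k-mers (both strands) form a sorted probe set;
    every genome k-mer is matched against it, so genome-side multiplicity
    of the probed codes is obtained without a full genome index.  Anchor
    definition and chaining are identical to
    :func:`find_orthologous_region`.
    """
    k = config.anchor_kmer
    code_parts, bait_parts, pos_parts, strand_parts = [], [], [], []
    for bi, bait in enumerate(baits):
        idx, fwd = _bait_unique_kmers(bait, k)
        for strand_code, codes in ((0, fwd), (1, rc_codes(fwd, k))):
            code_parts.append(codes)
            bait_parts.append(np.full(idx.size, bi, dtype=np.int32))
            pos_parts.append(idx)
            strand_parts.append(np.full(idx.size, strand_code,
                                        dtype=np.int8))
    if not code_parts:
        return {b.bait_id: None for b in baits}
    U = np.concatenate(code_parts)
    B = np.concatenate(bait_parts)
    P = np.concatenate(pos_parts)
    S = np.concatenate(strand_parts)
    order = np.argsort(U, kind="stable")
    U, B, P, S = U[order], B[order], P[order], S[order]
    # codes shared between baits (or strands) stay valid anchors for each
    # owner; ``head`` marks the first row of every distinct code run and
    # genome matches are later fanned out over the whole run
    head = np.ones(U.size, dtype=bool)
    head[1:] = U[1:] != U[:-1]
    run_id = np.cumsum(head) - 1           # row -> distinct-code index
    uniq_codes = U[head]
    run_starts = np.nonzero(head)[0]
    run_ends = np.append(run_starts[1:], U.size)

    # cheap low-bits membership prefilter before the binary search
    bits = 22
    lowmask = (1 << bits) - 1
    table = np.zeros(1 << bits, dtype=bool)
    table[uniq_codes & lowmask] = True

    cidx_parts, chrom_parts, gpos_parts = [], [], []
    chrom_names = list(genome.chromosomes)
    for ci, chrom in enumerate(chrom_names):
        codes_g, valid_g = kmer_codes(encode(genome.chromosomes[chrom]), k)
        if codes_g.size == 0:
            continue
        cand = table[codes_g & lowmask]
        cand &= valid_g
        gp0 = np.nonzero(cand)[0]
        sub = codes_g[gp0]
        ii = np.searchsorted(uniq_codes, sub)
        iic = np.minimum(ii, uniq_codes.size - 1)
        m = uniq_codes[iic] == sub
        gp = gp0[m]
        cidx_parts.append(iic[m])
        chrom_parts.append(np.full(gp.size, ci, dtype=np.int32))
        gpos_parts.append(gp)
    if not cidx_parts:
        return {b.bait_id: None for b in baits}
    cidx = np.concatenate(cidx_parts)
    chromi = np.concatenate(chrom_parts)
    gpos = np.concatenate(gpos_parts)
    counts = np.bincount(cidx, minlength=uniq_codes.size)
    single = counts[cidx] == 1
    cidx, chromi, gpos = cidx[single], chromi[single], gpos[single]

    # fan genome matches out to every probe row sharing the code
    reps = (run_ends - run_starts)[cidx]
    uidx = np.repeat(run_starts[cidx], reps) + \
        _within_run_offsets(reps)
    chromi = np.repeat(chromi, reps)
    gpos = np.repeat(gpos, reps)

    bset, sset, ppos = B[uidx], S[uidx], P[uidx]
    results: dict[str, Optional[OrthologHit]] = {}
    for bi, bait in enumerate(baits):
        mb = bset == bi
        groups = []
        for strand_code, strand in ((0, "+"), (1, "-")):
            ms = mb & (sset == strand_code)
            for ci in np.unique(chromi[ms]):
                mc = ms & (chromi == ci)
                groups.append((strand, chrom_names[int(ci)],
                               ppos[mc], gpos[mc]))
        results[bait.bait_id] = _select_hit(bait, genome, groups, config)
    return results


def trim_to_bait(hit: OrthologHit, bait_len: int, k: int) -> OrthologHit:
    """Trim hit padding so the sequence corresponds end-to-end to the bait.

    The retained slice extends the outermost anchors by exactly the
    unanchored bait overhang on each side (clipped to the hit), so global
    alignment does not see the 2-kb padding as terminal insertions.
    """
    b0, q0 = int(hit.anchors_bait[0]), int(hit.anchors_seq[0])
    b1, q1 = int(hit.anchors_bait[-1]), int(hit.anchors_seq[-1])
    lead = min(q0, b0)
    tail = min(len(hit.sequence) - (q1 + k), bait_len - (b1 + k))
    s = q0 - lead
    e = q1 + k + tail
    seq = hit.sequence[s:e]
    if hit.strand == "+":
        new_iv = GenomicInterval(hit.interval.chrom, hit.interval.start + s,
                                 hit.interval.start + e, "+")
    else:
        new_iv = GenomicInterval(hit.interval.chrom,
                                 hit.interval.end - e,
                                 hit.interval.end - s, "-")
    return OrthologHit(
        source_accession=hit.source_accession,
        interval=new_iv,
        sequence=seq,
        strand=hit.strand,
        anchor_count=hit.anchor_count,
        anchor_span_fraction=hit.anchor_span_fraction,
        anchors_bait=hit.anchors_bait,
        anchors_seq=hit.anchors_seq - s,
        ambiguous=hit.ambiguous,
    )


def assemble_ortholog_set(bait: BaitRegion, genomes: list[GenomeAssembly],
                          config: PipelineConfig,
                          indexes: Optional[dict[str, KmerIndex]] = None
                          ) -> OrthologSet | OrthologRejection:
    """Collect at most one hit per genome; reject when the member count
    (hits + bait) stays below ``min_ortholog_members``."""
    if not genomes:
        raise ValueError("at least one non-reference genome required")
    hits: list[OrthologHit] = []
    missing: dict[str, str] = {}
    for genome in genomes:
        idx = indexes.get(genome.accession_id) if indexes else None
        hit = find_orthologous_region(bait, genome, config, idx)
        if hit is None:
            missing[genome.accession_id] = "no co-linear anchor chain"
        else:
            hits.append(hit)
    oset = OrthologSet(bait=bait, hits=hits, missing=missing)
    if not oset.accepted(config.min_ortholog_members):
        return OrthologRejection(bait=bait, member_count=oset.member_count,
                                 missing=missing)
    return oset
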