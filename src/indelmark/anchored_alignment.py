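"""Reference-anchored alignment of ortholog sequences to a bait.

Two layers:

* a banded global affine-gap aligner (``banded_global_align``) whose
  in-row horizontal-gap recurrence is rewritten as a running prefix
  maximum, which keeps every row a handful of vectorised array operations
  while remaining exactly the textbook three-state DP;
* a piecewise aligner (``align_with_anchors``) that glues exact anchor
  blocks from the orthology chain and runs the banded DP only on the
  short regions between them, which is what makes 30-100-kb baits cheap.

Pairwise alignments are then projected onto reference coordinates: each
bait base is one column, member deletions are gap runs over reference
intervals, and member insertions are stored as (reference position,
inserted sequence).  The projection is lossless; no multi-member column
merging is attempted (InDel screening compares event lengths instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .kmer import encode

NEG = -1.0e30
_TOL = 1e-6


class BandOverflowError(RuntimeError):
    """Optimal path hit the band edge even after 4x band doubling."""


@dataclass
class PairwiseAlignment:
    query_id: str
    aligned_bait: str
    aligned_query: str
    score: float
    identity: float

    def validate(self) -> None:
        if len(self.aligned_bait) != len(self.aligned_query):
            raise ValueError("gapped rows differ in length")
        for ca, cb in zip(self.aligned_bait, self.aligned_query):
            if ca == "-" and cb == "-":
                raise ValueError("column gapped in both rows")

    @property
    def bait_seq(self) -> str:
        return self.aligned_bait.replace("-", "")

    @property
    def query_seq(self) -> str:
        return self.aligned_query.replace("-", "")


def _banded_core(a: str, b: str, match: float, mismatch: float,
                 gap_open: float, gap_extend: float, w: int
                 ) -> tuple[Optional[tuple[list[str], list[str], float]], bool]:
    """One banded DP attempt; returns (result, overflowed)."""
    n, m = len(a), len(b)
    dlo = min(0, m - n) - w
    dhi = max(0, m - n) + w
    W = dhi - dlo + 1
    if (n + 1) * W > 20_000_000:
        raise MemoryError("band too large; align with anchors instead")
    ea = encode(a).astype(np.int16)
    eb = encode(b).astype(np.int16)
    # non-ACGT characters never match each other
    ea[ea > 3] = 4
    eb[eb > 3] = 5
    M = np.full((n + 1, W), NEG)
    X = np.full((n + 1, W), NEG)
    Y = np.full((n + 1, W), NEG)
    d_arr = np.arange(W, dtype=np.int64)
    j0 = dlo + d_arr
    M[0, j0 == 0] = 0.0
    lead = (j0 >= 1) & (j0 <= m)
    Y[0, lead] = gap_open + gap_extend * j0[lead]
    ge, go = gap_extend, gap_open
    for i in range(1, n + 1):
        jrow = i + dlo + d_arr
        ok_m = (jrow >= 1) & (jrow <= m)
        jc = np.clip(jrow - 1, 0, m - 1)
        s = np.where(eb[jc] == ea[i - 1], match, mismatch)
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        Mi = prev_best + s
        Mi[~ok_m] = NEG
        M[i] = Mi
        up_my = np.maximum(M[i - 1], Y[i - 1])
        Xi = np.maximum(
            np.concatenate((up_my[1:], [NEG])) + go + ge,
            np.concatenate((X[i - 1][1:], [NEG])) + ge,
        )
        ok_x = (jrow >= 0) & (jrow <= m)
        Xi[~ok_x] = NEG
        X[i] = Xi
        t = np.maximum(Mi, Xi) + go - ge * jrow
        c = np.maximum.accumulate(t)
        Yi = ge * jrow + np.concatenate(([NEG], c[:-1]))
        Yi[~ok_m] = NEG
        Y[i] = Yi
    d_f = m - n - dlo
    score = max(M[n, d_f], X[n, d_f], Y[n, d_f])
    if score <= NEG / 2:
        return None, True
    # traceback
    cols_a: list[str] = []
    cols_b: list[str] = []
    i, d = n, d_f
    state = ("M", "X", "Y")[int(np.argmax([M[n, d_f], X[n, d_f], Y[n, d_f]]))]
    dmin = dmax = d
    steps = 0
    while not (i == 0 and i + dlo + d == 0):
        steps += 1
        if steps > n + m + 5:
            raise RuntimeError("traceback failed to terminate")
        j = i + dlo + d
        dmin, dmax = min(dmin, d), max(dmax, d)
        if state == "M":
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            mx = max(M[i - 1, d], X[i - 1, d], Y[i - 1, d])
            for st, v in (("M", M[i - 1, d]), ("X", X[i - 1, d]),
                          ("Y", Y[i - 1, d])):
                if v >= mx - _TOL:
                    state = st
                    break
            i -= 1
        elif state == "X":
            cols_a.append(a[i - 1])
            cols_b.append("-")
            val = X[i, d]
            cand_m = M[i - 1, d + 1] + go + ge if d + 1 < W else NEG
            cand_y = Y[i - 1, d + 1] + go + ge if d + 1 < W else NEG
            cand_x = X[i - 1, d + 1] + ge if d + 1 < W else NEG
            if abs(val - cand_m) <= _TOL:
                state = "M"
            elif abs(val - cand_y) <= _TOL:
                state = "Y"
            elif abs(val - cand_x) <= _TOL:
                state = "X"
            else:  # numerical fallback: closest candidate
                state = ("M", "Y", "X")[int(np.argmin(
                    [abs(val - cand_m), abs(val - cand_y), abs(val - cand_x)]))]
            i -= 1
            d += 1
        else:  # Y
            cols_a.append("-")
            cols_b.append(b[j - 1])
            val = Y[i, d]
            cand_m = M[i, d - 1] + go + ge if d - 1 >= 0 else NEG
            cand_x = X[i, d - 1] + go + ge if d - 1 >= 0 else NEG
            cand_y = Y[i, d - 1] + ge if d - 1 >= 0 else NEG
            if abs(val - cand_m) <= _TOL:
                state = "M"
            elif abs(val - cand_x) <= _TOL:
                state = "X"
            elif abs(val - cand_y) <= _TOL:
                state = "Y"
            else:
                state = ("M", "X", "Y")[int(np.argmin(
                    [abs(val - cand_m), abs(val - cand_x), abs(val - cand_y)]))]
            d -= 1
    full_cover = (dlo <= -n) and (dhi >= m)
    overflow = not full_cover and (
        (dmin == 0 and dlo > -n) or (dmax == W - 1 and dhi < m))
    if overflow:
        return None, True
    return (cols_a[::-1], cols_b[::-1], float(score)), False


def banded_global_align(a: str, b: str, match: float = 1.0,
                        mismatch: float = -2.0, gap_open: float = -6.0,
                        gap_extend: float = -0.2, band_width: int = 500,
                        query_id: str = "query") -> PairwiseAlignment:
    """Optimal global affine-gap alignment within a diagonal band.

    A gap of length L costs ``gap_open + L * gap_extend``.  When the
    optimal path touches the band edge, the band is doubled automatically
    (up to 4x the requested width) before :class:`BandOverflowError`.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    w = max(1, band_width)
    for scale in (1, 2, 4):
        res, overflow = _banded_core(a, b, match, mismatch, gap_open,
                                     gap_extend, w * scale)
        if not overflow:
            cols_a, cols_b, score = res
            return _finish(cols_a, cols_b, score, query_id)
        if (w * scale) >= len(a) + len(b):
            break
    raise BandOverflowError(
        f"optimal path exceeds band of width {w * 4}")


def _finish(cols_a: list[str], cols_b: list[str], score: float,
            query_id: str) -> PairwiseAlignment:
    ncols = len(cols_a)
    matches = sum(1 for x, y in zip(cols_a, cols_b) if x == y and x != "-")
    aln = PairwiseAlignment(
        query_id=query_id,
        aligned_bait="".join(cols_a),
        aligned_query="".join(cols_b),
        score=score,
        identity=matches / ncols if ncols else 0.0,
    )
    aln.validate()
    return aln


def align_with_anchors(a: str, b: str, anchors_a: Sequence[int],
                       anchors_b: Sequence[int], k: int,
                       match: float = 1.0, mismatch: float = -2.0,
                       gap_open: float = -6.0, gap_extend: float = -0.2,
                       band_width: int = 500,
                       query_id: str = "query") -> PairwiseAlignment:
    """Piecewise global alignment glued at exact k-mer anchor blocks."""
    # collapse anchors into maximal exact, co-diagonal blocks
    blocks: list[tuple[int, int, int]] = []  # (a_start, b_start, length)
    cur = None
    for ab, qb in zip(anchors_a, anchors_b):
        ab, qb = int(ab), int(qb)
        if a[ab:ab + k] != b[qb:qb + k]:
            continue  # defensive: anchors must be exact matches
        if cur is None:
            cur = [ab, qb, k]
            continue
        bs, qs, ln = cur
        if ab - qb == bs - qs and bs <= ab <= bs + ln:
            cur[2] = max(ln, ab + k - bs)
        elif ab >= bs + ln and qb >= qs + ln:
            blocks.append(tuple(cur))
            cur = [ab, qb, k]
        # else: conflicting overlap; skip anchor
    if cur is not None:
        blocks.append(tuple(cur))
    if not blocks:
        return banded_global_align(a, b, match, mismatch, gap_open,
                                   gap_extend, band_width, query_id)
    cols_a: list[str] = []
    cols_b: list[str] = []
    score = 0.0
    pa = pb = 0
    for bs, qs, ln in blocks + [(len(a), len(b), 0)]:
        seg_a, seg_b = a[pa:bs], b[pb:qs]
        L = len(seg_a)
        mm = sum(x != y for x, y in zip(seg_a, seg_b)) \
            if L == len(seg_b) and 0 < L <= 8 else -1
        diag_score = (L - mm) * match + mm * mismatch if mm >= 0 else 0.0
        gapped_bound = (L - 1) * match + 2 * (gap_open + gap_extend)
        if mm >= 0 and diag_score >= gapped_bound:
            # equal-length micro-segment where the diagonal provably beats
            # any gapped alternative (two gap opens cost more than the
            # observed mismatches)
            cols_a.extend(seg_a)
            cols_b.extend(seg_b)
            score += sum(match if x == y else mismatch
                         for x, y in zip(seg_a, seg_b))
        elif seg_a and seg_b:
            w0 = max(16, abs(len(seg_a) - len(seg_b)) + 16)
            try:
                sub = banded_global_align(seg_a, seg_b, match, mismatch,
                                          gap_open, gap_extend, w0)
            except BandOverflowError:
                sub = banded_global_align(
                    seg_a, seg_b, match, mismatch, gap_open, gap_extend,
                    len(seg_a) + len(seg_b))
            cols_a.extend(sub.aligned_bait)
            cols_b.extend(sub.aligned_query)
            score += sub.score
        elif seg_a:
            cols_a.extend(seg_a)
            cols_b.extend("-" * len(seg_a))
            score += gap_open + gap_extend * len(seg_a)
        elif seg_b:
            cols_a.extend("-" * len(seg_b))
            cols_b.extend(seg_b)
            score += gap_open + gap_extend * len(seg_b)
        if ln:
            cols_a.extend(a[bs:bs + ln])
            cols_b.extend(b[qs:qs + ln])
            score += match * ln
        pa, pb = bs + ln, qs + ln
    return _finish(cols_a, cols_b, score, query_id)


def align_to_bait(bait_seq: str, ortho_seq: str, *,
                  anchors: Optional[tuple[Sequence[int], Sequence[int]]] = None,
                  anchor_k: int = 15,
                  match: float = 1.0, mismatch: float = -2.0,
                  gap_open: float = -6.0, gap_extend: float = -0.2,
                  band_width: int = 500,
                  query_id: str = "query") -> PairwiseAlignment:
    """Align one ortholog to the bait, using the anchor chain if given."""
    if anchors is not None:
        return align_with_anchors(bait_seq, ortho_seq, anchors[0],
                                  anchors[1], anchor_k, match, mismatch,
                                  gap_open, gap_extend, band_width, query_id)
    return banded_global_align(bait_seq, ortho_seq, match, mismatch,
                               gap_open, gap_extend, band_width, query_id)


# ---------------------------------------------------------------------------
# reference-projected MSA
# ---------------------------------------------------------------------------

@dataclass
class MemberEvents:
    """Sparse difference set of one member relative to the bait."""

    deletions: list[tuple[int, int]] = field(default_factory=list)
    insertions: list[tuple[int, str]] = field(default_factory=list)
    substitutions: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class AnchoredMSA:
    bait_id: str
    bait_seq: str
    member_ids: list[str]
    events: dict[str, MemberEvents]
    missing: list[str] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.bait_seq)

    @property
    def member_count(self) -> int:
        return len(self.member_ids) + 1  # bait included

    def member_length(self, member_id: str) -> int:
        ev = self.events[member_id]
        dele = sum(e - s for s, e in ev.deletions)
        ins = sum(len(s) for _, s in ev.insertions)
        return len(self.bait_seq) - dele + ins


def project_to_msa(bait_id: str, bait_seq: str,
                   alignments: list[PairwiseAlignment],
                   missing: Optional[list[str]] = None) -> AnchoredMSA:
    """Project pairwise alignments into reference coordinates (lossless).

    InDel events are left-aligned so positions are reproducible across
    aligner variants with different (equivalent-score) gap placement.
    """
    events: dict[str, MemberEvents] = {}
    member_ids: list[str] = []
    for aln in alignments:
        if aln.bait_seq != bait_seq:
            raise ValueError(
                f"{aln.query_id}: degapped bait row differs from bait")
        events[aln.query_id] = _extract_events(bait_seq, aln)
        member_ids.append(aln.query_id)
    return AnchoredMSA(bait_id=bait_id, bait_seq=bait_seq,
                       member_ids=member_ids, events=events,
                       missing=list(missing or []))


def _extract_events(bait_seq: str, aln: PairwiseAlignment) -> MemberEvents:
    ev = MemberEvents()
    rp = 0
    del_start = -1
    ins_seq: list[str] = []
    barrier = 0  # leftmost position an event may shift into

    def flush_del(end: int) -> None:
        nonlocal del_start, barrier
        s, e = del_start, end
        while s > barrier and bait_seq[s - 1] == bait_seq[e - 1]:
            s -= 1
            e -= 1
        ev.deletions.append((s, e))
        barrier = e
        del_start = -1

    def flush_ins(pos: int) -> None:
        nonlocal ins_seq, barrier
        seq = "".join(ins_seq)
        p = pos
        while p > barrier and bait_seq[p - 1] == seq[-1]:
            seq = seq[-1] + seq[:-1]
            p -= 1
        ev.insertions.append((p, seq))
        barrier = p
        ins_seq = []

    for ca, cb in zip(aln.aligned_bait, aln.aligned_query):
        if ca != "-" and cb != "-":
            if del_start >= 0:
                flush_del(rp)
            if ins_seq:
                flush_ins(rp)
            if ca != cb:
                ev.substitutions.append((rp, cb))
                barrier = rp + 1
            rp += 1
        elif cb == "-":
            if ins_seq:
                flush_ins(rp)
            if del_start < 0:
                del_start = rp
            rp += 1
        else:  # ca == '-'
            if del_start >= 0:
                flush_del(rp)
            ins_seq.append(cb)
    if del_start >= 0:
        flush_del(rp)
    if ins_seq:
        flush_ins(rp)
    return ev


def deproject(msa: AnchoredMSA, member_id: str) -> str:
    """Reconstruct a member sequence from the bait and its event set."""
    ev = msa.events[member_id]
    subs = dict(ev.substitutions)
    del_mask = np.zeros(len(msa.bait_seq), dtype=bool)
    for s, e in ev.deletions:
        del_mask[s:e] = True
    ins_at: dict[int, str] = {}
    for p, seq in ev.insertions:
        ins_at[p] = ins_at.get(p, "") + seq
    parts: list[str] = []
    for p, base in enumerate(msa.bait_seq):
        if p in ins_at:
            parts.append(ins_at[p])
        if del_mask[p]:
            continue
        parts.append(subs.get(p, base))
    L = len(msa.bait_seq)
    if L in ins_at:
        parts.append(ins_at[L])
    return "".join(parts)


def msa_to_fasta(msa: AnchoredMSA, path) -> None:
    """Emit the projected alignment as aligned multi-FASTA.

    Reference-anchored view for eyeballing in an alignment editor: one
    column per bait base, expanded at member insertion sites; the first
    record is the bait itself.
    """
    L = len(msa.bait_seq)
    ins_width = np.zeros(L + 1, dtype=np.int64)
    for ev in msa.events.values():
        at: dict[int, int] = {}
        for p, seq in ev.insertions:
            at[p] = at.get(p, 0) + len(seq)
        for p, w in at.items():
            ins_width[p] = max(ins_width[p], w)

    def render(member: Optional[str]) -> str:
        if member is None:
            subs, dels, ins = {}, set(), {}
        else:
            ev = msa.events[member]
            subs = dict(ev.substitutions)
            dels = {p for s, e in ev.deletions for p in range(s, e)}
            ins = {}
            for p, seq in ev.insertions:
                ins[p] = ins.get(p, "") + seq
        parts: list[str] = []
        for p in range(L + 1):
            if ins_width[p]:
                chunk = ins.get(p, "")
                parts.append(chunk + "-" * (int(ins_width[p]) - len(chunk)))
            if p < L:
                if p in dels:
                    parts.append("-")
                else:
                    parts.append(subs.get(p, msa.bait_seq[p]))
        return "".join(parts)

    with open(path, "w") as out:
        out.write(f">{msa.bait_id}\n{render(None)}\n")
        for member in msa.member_ids:
            out.write(f">{member}\n{render(member)}\n")


def polymorphic_positions(msa: AnchoredMSA) -> np.ndarray:
    """Boolean array over reference columns: True where any member
    differs (substitution, deletion cover, or insertion junction)."""
    flag = np.zeros(len(msa.bait_seq), dtype=bool)
    for ev in msa.events.values():
        for p, _ in ev.substitutions:
            flag[p] = True
        for s, e in ev.deletions:
            flag[s:e] = True
        for p, _ in ev.insertions:
            if p < flag.size:
                flag[p] = True
            if p > 0:
                flag[p - 1] = True
    return flag
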