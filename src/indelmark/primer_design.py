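"""Primer-pair design in conserved flanks around a selected InDel.

Primers are enumerated inside flank windows that are column-identical
across all aligned members (so both alleles amplify with even efficiency),
filtered on length, nearest-neighbor melting temperature, GC content,
homopolymer runs and 3'-complementarity, and the pair minimising
``|longest-allele product - 300 bp|`` under the 100-500-bp product bounds
for every member is returned.  Genome-wide uniqueness is checked by exact
string scan of both strands.  Markers are named ``A`` + two-digit
chromosome + ``P`` + five-digit kb position.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .anchored_alignment import AnchoredMSA, polymorphic_positions
from .config import PipelineConfig
from .indel_screen import REF_MEMBER, DiagnosticCall, IndelBlock
from .seq_io import GenomeAssembly, GenomicInterval, MarkerRecord, revcomp

# ---------------------------------------------------------------------------
# nearest-neighbor melting temperature
# ---------------------------------------------------------------------------

# Unified nearest-neighbor duplex parameters (kcal/mol, cal/mol/K)
_NN: dict[str, tuple[float, float]] = {
    "AA": (-7.6, -21.3), "TT": (-7.6, -21.3),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT = (0.2, -5.7)
_TERM_AT = (2.2, 6.9)  # per terminal A/T pair
_R = 1.987  # cal/mol/K


def melting_temp(primer_seq: str, monovalent_mM: float = 50.0,
                 oligo_uM: float = 0.25) -> float:
    """Nearest-neighbor Tm (degC) of a primer against its perfect
    complement; 50 mM monovalent salt, 0.25 uM oligo by default.

    Salt is applied as an entropic correction
    ``dS += 0.368 (N-1) ln[Na+]``; the duplex initiation term and
    terminal-A/T penalties follow the unified parameter set.  Result is
    rounded to 0.01 degC and is deterministic.
    """
    seq = primer_seq.upper()
    if len(seq) < 10:
        raise ValueError("primer shorter than 10 nt")
    if re.search("[^ACGT]", seq):
        raise ValueError(f"ambiguity code in primer {primer_seq!r}")
    dh, ds = _INIT
    for end in (seq[0], seq[-1]):
        if end in "AT":
            dh += _TERM_AT[0]
            ds += _TERM_AT[1]
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i:i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * np.log(monovalent_mM / 1000.0)
    # primer in large excess over template: CT term is the primer conc.
    c = oligo_uM * 1e-6
    tm = (dh * 1000.0) / (ds + _R * np.log(c)) - 273.15
    return round(float(tm), 2)


# ---------------------------------------------------------------------------
# naming
# ---------------------------------------------------------------------------

def name_marker(chromosome_index: int, ref_position_bp: int) -> str:
    """``A`` + 2-digit chromosome + ``P`` + 5-digit kb position."""
    if not 1 <= chromosome_index <= 99:
        raise ValueError("chromosome index must be in [1, 99]")
    if ref_position_bp < 0:
        raise ValueError("position must be >= 0")
    kb = round(ref_position_bp / 1000)
    if kb >= 100_000:
        raise ValueError("kb position does not fit in 5 digits")
    return f"A{chromosome_index:02d}P{kb:05d}"


def decode_marker_name(name: str) -> tuple[int, int]:
    """Inverse of :func:`name_marker`: (chromosome index, kb position)."""
    m = re.fullmatch(r"A(\d{2})P(\d{5})", name)
    if not m:
        raise ValueError(f"not a marker name: {name!r}")
    return int(m.group(1)), int(m.group(2))


# ---------------------------------------------------------------------------
# conserved flank windows
# ---------------------------------------------------------------------------

def conserved_flank_windows(msa: AnchoredMSA, block: IndelBlock,
                            max_mismatch_columns: int = 0,
                            search_span: int = 250,
                            ) -> tuple[list[tuple[int, int]],
                                       list[tuple[int, int]]]:
    """Maximal conserved windows left and right of a block.

    A column is usable when at most ``max_mismatch_columns`` members carry
    a non-reference character there and no member has a gap or insertion
    junction.  Windows are clipped to ``search_span`` bp from the block
    edges (half the maximum product size by default).
    """
    L = len(msa.bait_seq)
    bad = _column_badness(msa) if max_mismatch_columns > 0 else \
        polymorphic_positions(msa)
    if max_mismatch_columns > 0:
        usable = bad <= max_mismatch_columns
    else:
        usable = ~bad
    left_lo = max(0, block.ref_start - search_span)
    right_hi = min(L, block.ref_end + search_span)
    left = _maximal_runs(usable, left_lo, block.ref_start)
    right = _maximal_runs(usable, block.ref_end, right_hi)
    return left, right


def _column_badness(msa: AnchoredMSA) -> np.ndarray:
    """Per-column count of members with a substitution; gap/insertion
    columns are poisoned (count above any threshold)."""
    L = len(msa.bait_seq)
    cnt = np.zeros(L, dtype=np.int32)
    big = 10 ** 6
    for ev in msa.events.values():
        for p, _ in ev.substitutions:
            cnt[p] += 1
        for s, e in ev.deletions:
            cnt[s:e] += big
        for p, _ in ev.insertions:
            if p < L:
                cnt[p] += big
            if p > 0:
                cnt[p - 1] += big
    return cnt


def _maximal_runs(usable: np.ndarray, lo: int, hi: int
                  ) -> list[tuple[int, int]]:
    runs = []
    s = None
    for p in range(lo, hi):
        if usable[p]:
            if s is None:
                s = p
        elif s is not None:
            runs.append((s, p))
            s = None
    if s is not None:
        runs.append((s, hi))
    return runs


def flank_budget(msa: AnchoredMSA, block: IndelBlock,
                 search_span: int = 250) -> int:
    """Pre-scan score for marker ranking: the smaller of the conserved
    stretches immediately adjacent to the block."""
    left, right = conserved_flank_windows(msa, block,
                                          search_span=search_span)
    ladj = next((e - s for s, e in reversed(left) if e == block.ref_start), 0)
    radj = next((e - s for s, e in right if s == block.ref_end), 0)
    return min(ladj, radj)


# ---------------------------------------------------------------------------
# primer pair design
# ---------------------------------------------------------------------------

@dataclass
class PrimerPair:
    forward_seq: str
    reverse_seq: str  # 5'->3' on the minus strand
    forward_ref_interval: GenomicInterval  # bait-local
    reverse_ref_interval: GenomicInterval
    tm_forward_c: float
    tm_reverse_c: float
    product_len_by_member: dict[str, int]


@dataclass
class DesignFailure:
    reason: str  # no_conserved_flank | no_feasible_primer | product_bounds


@dataclass
class Marker:
    name: str
    chrom: str
    position_bp: int  # 0-based reference coordinate of the block start
    primer_pair: PrimerPair
    block: IndelBlock
    diagnostic: DiagnosticCall
    # genome coordinates of the reference amplicon
    amplicon: GenomicInterval = None

    def to_record(self) -> MarkerRecord:
        pp = self.primer_pair
        return MarkerRecord(
            name=self.name,
            chrom=self.chrom,
            pos_1based=self.position_bp + 1,
            tier=self.diagnostic.tier,
            gap_bp=self.diagnostic.gap_bp,
            block_start_1based=self.block_start_1based,
            block_end_1based=self.block_end_1based,
            fwd_seq=pp.forward_seq,
            rev_seq=pp.reverse_seq,
            tm_f=pp.tm_forward_c,
            tm_r=pp.tm_reverse_c,
            amplicon_start_1based=self.amplicon.start_1based,
            amplicon_end_1based=self.amplicon.end_1based,
            product_ref=pp.product_len_by_member[REF_MEMBER],
            products=";".join(f"{m}={v}" for m, v in
                              sorted(pp.product_len_by_member.items())),
        )

    @property
    def block_start_1based(self) -> int:
        return self.position_bp + 1

    @property
    def block_end_1based(self) -> int:
        return self.position_bp + len(self.block.ref_interval)


_HOMOPOLYMER = re.compile(r"(.)\1{4,}")


def _primer_ok(seq: str, config: PipelineConfig) -> bool:
    if re.search("[^ACGT]", seq):
        return False
    gc = (seq.count("G") + seq.count("C")) / len(seq) * 100.0
    if not 30.0 <= gc <= 70.0:
        return False
    if _HOMOPOLYMER.search(seq):
        return False
    if seq[-1] == seq[-2] == seq[-3]:  # 3' end inside a homopolymer
        return False
    return True


def three_prime_complementarity(p1: str, p2: str) -> int:
    """Longest run of perfect complementarity involving the 3' terminus of
    ``p1`` annealed to ``p2`` (both given 5'->3')."""
    rc2 = revcomp(p2)
    best = 0
    tail = p1[-8:] if len(p1) > 8 else p1
    for L in range(len(tail), 0, -1):
        if tail[-L:] in rc2:
            best = L
            break
    return best


def _member_product(msa: AnchoredMSA, member: str, s: int, e: int) -> int:
    """Length of member sequence between reference positions s and e."""
    length = e - s
    ev = msa.events[member]
    for ds, de in ev.deletions:
        length -= max(0, min(de, e) - max(ds, s))
    for p, seq in ev.insertions:
        if s < p < e:
            length += len(seq)
    return length


class _DeltaIndex:
    """Per-member cumulative indel deltas for fast product-length lookup.

    Valid when no event straddles the query bounds, which holds for
    primer sites inside conserved windows (gap-free by construction).
    """

    def __init__(self, msa: AnchoredMSA):
        self._tables: dict[str, tuple[list[int], list[int]]] = {}
        for member in msa.member_ids:
            ev = msa.events[member]
            items = [(ds, -(de - ds)) for ds, de in ev.deletions]
            items += [(p, len(seq)) for p, seq in ev.insertions if p > 0]
            items.sort()
            pos = [p for p, _ in items]
            cum = [0]
            for _, d in items:
                cum.append(cum[-1] + d)
            self._tables[member] = (pos, cum)

    def product(self, member: str, s: int, e: int) -> int:
        pos, cum = self._tables[member]
        lo = bisect.bisect_right(pos, s)
        hi = bisect.bisect_left(pos, e)
        return (e - s) + cum[hi] - cum[lo]


def design_primer_pair(msa: AnchoredMSA, block: IndelBlock,
                       config: PipelineConfig,
                       bait_mask: Optional[np.ndarray] = None,
                       max_candidates_per_side: int = 150,
                       ) -> PrimerPair | DesignFailure:
    """Choose the primer pair around a block, or a machine-readable
    failure (no conserved flank / no feasible primer / product bounds)."""
    search_span = config.product_max // 2
    left, right = conserved_flank_windows(msa, block,
                                          search_span=search_span)
    if not left or not right:
        return DesignFailure("no_conserved_flank")
    fwd: list[tuple[int, int, float]] = []  # (start, length, tm)
    rev: list[tuple[int, int, float]] = []
    for s, e in left:
        hi = min(e, block.ref_start)
        for start in range(s, hi):
            for ln in range(config.primer_len_min,
                            config.primer_len_max + 1):
                if start + ln > hi:
                    break
                seq = msa.bait_seq[start:start + ln]
                if bait_mask is not None and bait_mask[start:start + ln].any():
                    continue
                if not _primer_ok(seq, config):
                    continue
                tm = melting_temp(seq)
                if config.primer_tm_min_c <= tm <= config.primer_tm_max_c:
                    fwd.append((start, ln, tm))
    for s, e in right:
        lo = max(s, block.ref_end)
        for start in range(lo, e):
            for ln in range(config.primer_len_min,
                            config.primer_len_max + 1):
                if start + ln > e:
                    break
                site = msa.bait_seq[start:start + ln]
                if bait_mask is not None and bait_mask[start:start + ln].any():
                    continue
                seq = revcomp(site)
                if not _primer_ok(seq, config):
                    continue
                tm = melting_temp(seq)
                if config.primer_tm_min_c <= tm <= config.primer_tm_max_c:
                    rev.append((start, ln, tm))
    if not fwd or not rev:
        return DesignFailure("no_feasible_primer")
    # deterministic thinning: keep candidates closest to the block
    fwd.sort(key=lambda c: (block.ref_start - (c[0] + c[1]), c[0], c[1]))
    rev.sort(key=lambda c: (c[0] - block.ref_end, c[0], c[1]))
    fwd = fwd[:max_candidates_per_side]
    rev = rev[:max_candidates_per_side]

    # self-complementarity is a per-primer property: filter once
    fwd = [(s, ln, tm) for s, ln, tm in fwd
           if three_prime_complementarity(msa.bait_seq[s:s + ln],
                                          msa.bait_seq[s:s + ln]) <= 4]
    rev = [(s, ln, tm) for s, ln, tm in rev
           if three_prime_complementarity(revcomp(msa.bait_seq[s:s + ln]),
                                          revcomp(msa.bait_seq[s:s + ln]))
           <= 4]
    members = list(msa.member_ids)
    deltas = _DeltaIndex(msa)
    rev.sort()
    rev_starts = [c[0] for c in rev]
    margin = 200  # indel deltas may stretch member products this far
    pairs: list[tuple[float, int, int, tuple]] = []
    pmin, pmax = config.product_min, config.product_max
    for fs, fl, ftm in fwd:
        lo = bisect.bisect_left(rev_starts, fs + pmin - margin)
        hi = bisect.bisect_right(rev_starts,
                                 fs + pmax - config.primer_len_min + 1)
        for rs, rl, rtm in rev[lo:hi]:
            if abs(ftm - rtm) > config.max_tm_difference_c:
                continue
            s, e = fs, rs + rl
            if not pmin <= e - s <= pmax:
                continue
            products = {REF_MEMBER: e - s}
            ok = True
            for m in members:
                p = deltas.product(m, s, e)
                if not pmin <= p <= pmax:
                    ok = False
                    break
                products[m] = p
            if not ok:
                continue
            longest = max(products.values())
            pairs.append((abs(longest - config.target_product_bp), fs, rs,
                          (fs, fl, ftm, rs, rl, rtm, products)))
    if not pairs:
        return DesignFailure("product_bounds")
    pairs.sort(key=lambda x: (x[0], x[1], x[2]))
    chosen = None
    for _, _, _, data in pairs:
        fs, fl, ftm, rs, rl, rtm, products = data
        fseq = msa.bait_seq[fs:fs + fl]
        rseq = revcomp(msa.bait_seq[rs:rs + rl])
        if three_prime_complementarity(fseq, rseq) <= 4 and \
           three_prime_complementarity(rseq, fseq) <= 4:
            chosen = data
            break
    if chosen is None:
        return DesignFailure("product_bounds")
    fs, fl, ftm, rs, rl, rtm, products = chosen
    chrom = block.ref_interval.chrom
    return PrimerPair(
        forward_seq=msa.bait_seq[fs:fs + fl],
        reverse_seq=revcomp(msa.bait_seq[rs:rs + rl]),
        forward_ref_interval=GenomicInterval(chrom, fs, fs + fl, "+"),
        reverse_ref_interval=GenomicInterval(chrom, rs, rs + rl, "-"),
        tm_forward_c=ftm,
        tm_reverse_c=rtm,
        product_len_by_member=products,
    )


# ---------------------------------------------------------------------------
# uniqueness
# ---------------------------------------------------------------------------

def count_occurrences(pattern: str, text: str) -> int:
    """Overlapping occurrence count of ``pattern`` in ``text``."""
    count = 0
    idx = text.find(pattern)
    while idx >= 0:
        count += 1
        idx = text.find(pattern, idx + 1)
    return count


def uniqueness_check(primer_pair: PrimerPair,
                     reference: GenomeAssembly) -> str:
    """``unique`` iff each primer (with its reverse complement) occurs
    exactly once in the reference genome; exact full-length matching."""
    for primer in (primer_pair.forward_seq, primer_pair.reverse_seq):
        total = 0
        rc = revcomp(primer)
        for seq in reference.chromosomes.values():
            total += count_occurrences(primer, seq)
            total += count_occurrences(rc, seq)
        if total != 1:
            return "multi"
    return "unique"
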