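"""Independent brute-force oracles used by the test suite only.

These deliberately avoid the implementation's data structures: the
alignment oracle is a plain per-cell dynamic program, the binding-site
oracle slides a window over every position, and the diagnostic oracle
evaluates the cultivar/wild quantifier by explicit double loop.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

NEG = -1.0e30

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def affine_global_score(a: str, b: str, match: float = 1.0,
                        mismatch: float = -2.0, gap_open: float = -6.0,
                        gap_extend: float = -0.2) -> float:
    """Unbanded three-state affine-gap global alignment score."""
    n, m = len(a), len(b)
    go, ge = gap_open, gap_extend
    Mp = [NEG] * (m + 1)
    Xp = [NEG] * (m + 1)
    Yp = [NEG] * (m + 1)
    Mp[0] = 0.0
    for j in range(1, m + 1):
        Yp[j] = go + ge * j
    for i in range(1, n + 1):
        Mi = [NEG] * (m + 1)
        Xi = [NEG] * (m + 1)
        Yi = [NEG] * (m + 1)
        Xi[0] = max(Mp[0] + go + ge, Xp[0] + ge)
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            Mi[j] = max(Mp[j - 1], Xp[j - 1], Yp[j - 1]) + s
            Xi[j] = max(Mp[j] + go + ge, Yp[j] + go + ge, Xp[j] + ge)
            Yi[j] = max(Mi[j - 1] + go + ge, Xi[j - 1] + go + ge,
                        Yi[j - 1] + ge)
        Mp, Xp, Yp = Mi, Xi, Yi
    return max(Mp[m], Xp[m], Yp[m])


def scan_binding_sites(primer: str, sequence: str, max_mismatch: int = 2,
                       three_prime_exact_len: int = 3
                       ) -> list[tuple[int, str]]:
    """Position-by-position window comparison over the whole sequence."""
    enc = np.frombuffer(sequence.encode(), dtype=np.uint8)
    out: list[tuple[int, str]] = []
    t = three_prime_exact_len
    for strand in "+-":
        target = primer if strand == "+" else revcomp(primer)
        tarr = np.frombuffer(target.encode(), dtype=np.uint8)
        L = tarr.size
        if enc.size < L:
            continue
        win = sliding_window_view(enc, L)
        ok = (win != tarr).sum(axis=1) <= max_mismatch
        if strand == "+":
            ok &= (win[:, L - t:] == tarr[L - t:]).all(axis=1)
        else:
            ok &= (win[:, :t] == tarr[:t]).all(axis=1)
        out.extend((int(p), strand) for p in np.nonzero(ok)[0])
    return sorted(out)


def diagnostic_tier_bruteforce(alleles: dict[str, int],
                               groups: dict[str, str],
                               min_gap: int) -> tuple[str, int]:
    """(tier, gap) by explicit evaluation over every cultivar/wild pair."""
    cult = [v for k, v in alleles.items()
            if groups.get(k, "").startswith("cultivar")]
    wild = [v for k, v in alleles.items() if groups.get(k) == "wild"]
    if not cult:
        raise ValueError("no cultivar")
    diffs = [abs(c - w) for c in cult for w in wild]
    qual = [d for d in diffs if d >= min_gap]
    if not wild or not qual:
        return "none", 0
    if len(qual) == len(diffs):
        return "full", min(qual)
    return "partial", min(qual)


def kmer_multiplicity_bruteforce(genome: dict[str, str], k: int
                                 ) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in genome.values():
        for i in range(len(seq) - k + 1):
            w = seq[i:i + k]
            counts[w] = counts.get(w, 0) + 1
    return counts
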