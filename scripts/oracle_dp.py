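"""Brute-force reference computations used by the acceptance script.

Kept deliberately separate from the package: a plain per-cell affine-gap
dynamic program and a position-by-position binding-site scan.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

NEG = -1.0e30

_RC = str.maketrans("ACGT", "TGCA")


def affine_global_score(a: str, b: str, match: float = 1.0,
                        mismatch: float = -2.0, gap_open: float = -6.0,
                        gap_extend: float = -0.2) -> float:
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
    enc = np.frombuffer(sequence.encode(), dtype=np.uint8)
    out: list[tuple[int, str]] = []
    t = three_prime_exact_len
    for strand in "+-":
        target = primer if strand == "+" else \
            primer.translate(_RC)[::-1]
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
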