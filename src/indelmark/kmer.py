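"""Integer k-mer encoding and a genome-wide multiplicity/location index.

Sequences are 2-bit encoded (A=0, C=1, G=2, T=3); any other IUPAC code
invalidates the k-mers covering it.  The index keeps a sorted array of all
k-mer codes with their source positions, which answers both multiplicity
queries (repeat-content estimation) and unique-k-mer location queries
(orthology anchoring) with binary search.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """2-bit base codes; 4 marks any non-ACGT character."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes of all k-mers of an encoded sequence.

    Returns ``(codes, valid)`` of length ``len(enc) - k + 1``; ``valid`` is
    False where the window contains a non-ACGT base (the code there is
    meaningless).  Requires ``k <= 31``.
    """
    if k > 31:
        raise ValueError("k must be <= 31 for 2-bit packing")
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    e = enc.astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes <<= 2
        codes |= e[j:j + n]
    bad = enc > 3
    if bad.any():
        cs = np.concatenate(([0], np.cumsum(bad.astype(np.int32))))
        valid = (cs[k:] - cs[:-k]) == 0
    else:
        valid = np.ones(n, dtype=bool)
    return codes, valid


def rc_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of packed k-mer codes."""
    out = np.zeros_like(codes)
    c = codes.copy()
    for _ in range(k):
        out = (out << 2) | (3 - (c & 3))
        c >>= 2
    return out


class KmerIndex:
    """Sorted-code index over one genome haplotype.

    Soft-masked positions may optionally be treated as invalid (repeat
    screening counts them as repeat content regardless of multiplicity).
    """

    def __init__(self, chrom_seqs: dict[str, str], k: int,
                 softmask: Optional[dict[str, np.ndarray]] = None):
        self.k = k
        self.chrom_names = list(chrom_seqs)
        self.chrom_lengths = {c: len(s) for c, s in chrom_seqs.items()}
        code_parts, valid_parts = [], []
        offsets = [0]
        for name in self.chrom_names:
            enc = encode(chrom_seqs[name])
            codes, valid = kmer_codes(enc, k)
            code_parts.append(codes)
            valid_parts.append(valid)
            offsets.append(offsets[-1] + codes.size)
        self._offsets = np.asarray(offsets, dtype=np.int64)
        codes = np.concatenate(code_parts) if code_parts else np.empty(0, np.int64)
        valid = np.concatenate(valid_parts) if valid_parts else np.empty(0, bool)
        # invalid windows get a sentinel code that never matches a query
        self._codes = np.where(valid, codes, np.int64(-1))
        self._sorted = np.sort(self._codes)
        self._order_: Optional[np.ndarray] = None  # built lazily

    @property
    def _order(self) -> np.ndarray:
        if self._order_ is None:
            order = np.argsort(self._codes, kind="stable")
            # rows with equal codes keep position order under stable sort,
            # matching self._sorted (also stable on values)
            self._order_ = order.astype(np.int64)
        return self._order_

    # -- queries -------------------------------------------------------
    def counts(self, query_codes: np.ndarray) -> np.ndarray:
        """Genome-wide multiplicity of each query code (0 for invalid)."""
        lo = np.searchsorted(self._sorted, query_codes, side="left")
        hi = np.searchsorted(self._sorted, query_codes, side="right")
        out = (hi - lo).astype(np.int64)
        out[query_codes < 0] = 0
        return out

    def locate_unique(self, query_codes: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
        """For query codes occurring exactly once genome-wide, return
        ``(query_index, global_position)`` arrays."""
        lo = np.searchsorted(self._sorted, query_codes, side="left")
        hi = np.searchsorted(self._sorted, query_codes, side="right")
        unique = (hi - lo == 1) & (query_codes >= 0)
        qidx = np.nonzero(unique)[0]
        gpos = self._order[lo[qidx]]
        return qidx, gpos

    def split_global(self, gpos: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
        """Map global k-mer start positions to (chrom index, local pos)."""
        ci = np.searchsorted(self._offsets, gpos, side="right") - 1
        return ci, gpos - self._offsets[ci]
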