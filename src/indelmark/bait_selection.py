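"""Bait window selection on the reference genome.

Bait sequences are 30-100-kb reference windows taken at ~1-Mb anchors along
each chromosome, avoiding repeat-rich regions.  "Repeat" is operationalised
as genome-wide k-mer multiplicity (k=21 by default): a window position is
repeat-flagged when the k-mer covering it occurs more than once in the
whole reference, or when the base is soft-masked or N.  An anchor whose
window exceeds the repeat budget is slid forward in half-window steps until
it becomes eligible or the next anchor is reached (that anchor is then
skipped, mirroring the gaps a repeat array such as a centromere forces).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import PipelineConfig
from .kmer import KmerIndex, encode, kmer_codes
from .seq_io import GenomeAssembly, GenomicInterval


@dataclass(frozen=True)
class BaitRegion:
    interval: GenomicInterval
    sequence: str
    repeat_fraction: float

    @property
    def bait_id(self) -> str:
        return f"{self.interval.chrom}:{self.interval.start_1based}-{self.interval.end_1based}"

    def __len__(self) -> int:
        return len(self.sequence)


def repeat_fraction(window_seq: str, k: int, genome_index: KmerIndex,
                    window_mask: Optional[np.ndarray] = None) -> float:
    """Fraction of window positions covered by a repeated/masked k-mer.

    Position ``p`` is flagged when the k-mer starting at ``p`` occurs more
    than once genome-wide or is invalid (contains N); the trailing ``k-1``
    positions inherit the final k-mer's status.  Soft-masked positions are
    flagged unconditionally.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    L = len(window_seq)
    if L < k:
        raise ValueError(f"window shorter than k ({L} < {k})")
    enc = encode(window_seq)
    codes, valid = kmer_codes(enc, k)
    counts = genome_index.counts(codes)
    km_bad = (counts > 1) | ~valid
    flagged = np.empty(L, dtype=bool)
    flagged[:km_bad.size] = km_bad
    flagged[km_bad.size:] = km_bad[-1]
    if window_mask is not None:
        flagged |= window_mask.astype(bool)
    flagged |= enc > 3  # N bases count as repeat content
    return float(flagged.mean())


def select_bait_windows(reference: GenomeAssembly, config: PipelineConfig,
                        genome_index: Optional[KmerIndex] = None,
                        window_len: Optional[int] = None) -> list[BaitRegion]:
    """Choose repeat-poor bait windows near every ~1-Mb anchor.

    ``window_len`` defaults to ``bait_min_len``; a longer window (up to
    ``bait_max_len``) can be requested for a second pass when a bait
    yields no usable InDel.
    """
    wlen = window_len if window_len is not None else config.bait_min_len
    if not config.bait_min_len <= wlen <= config.bait_max_len:
        raise ValueError("window_len outside [bait_min_len, bait_max_len]")
    if genome_index is None:
        genome_index = KmerIndex(reference.chromosomes, config.repeat_kmer)
    step = max(1, config.bait_min_len // 2)
    baits: list[BaitRegion] = []
    for chrom, seq in reference.chromosomes.items():
        L = len(seq)
        if L < wlen:
            continue
        mask = reference.mask_for(chrom)
        for anchor in range(0, L, config.bait_interval_bp):
            next_anchor = anchor + config.bait_interval_bp
            start = anchor
            while start < next_anchor and start + wlen <= L:
                window = seq[start:start + wlen]
                wmask = mask[start:start + wlen] if mask is not None else None
                rf = repeat_fraction(window, config.repeat_kmer,
                                     genome_index, wmask)
                if rf <= config.max_repeat_fraction:
                    baits.append(BaitRegion(
                        interval=GenomicInterval(chrom, start, start + wlen),
                        sequence=window,
                        repeat_fraction=rf,
                    ))
                    break
                start += step
    return baits


def write_bait_table(baits: list[BaitRegion], path) -> None:
    with open(path, "w") as out:
        out.write("chrom\tstart_1based\tend_1based\tlength\trepeat_fraction\n")
        for b in baits:
            iv = b.interval
            out.write(f"{iv.chrom}\t{iv.start_1based}\t{iv.end_1based}\t"
                      f"{len(b)}\t{b.repeat_fraction:.4f}\n")
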