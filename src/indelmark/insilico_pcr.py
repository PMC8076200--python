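"""In-silico PCR: primer binding, amplicon prediction, gel-band genotyping.

A primer binds where at most ``epcr_max_mismatch`` mismatches occur over
its full length and none in the 3'-terminal ``epcr_three_prime_exact``
bases (a mismatched 3' terminus aborts extension).  Binding search is
seed-and-verify: with at most q mismatches allowed, the primer is split
into q+1 parts of which at least one must match exactly, so exact substring
scans produce a small candidate list to verify -- equivalent to the
position-by-position scan but much faster on megabase genomes.

Band patterns merge amplicon lengths that differ by less than the agarose
resolution threshold (20 bp for 2.5-4.0% gels); more than two merged bands
is reported as ``excess_bands``, none as ``no_amplification``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import PipelineConfig
from .primer_design import Marker, PrimerPair
from .seq_io import GenomeAssembly, GenomicInterval, revcomp


@dataclass(frozen=True)
class Amplicon:
    interval: GenomicInterval
    length: int
    haplotype: int  # 1 or 2


@dataclass
class BandSet:
    accession_id: str
    band_lengths: list[float]          # after gel merging, sorted
    raw_amplicons: list[Amplicon]
    status: str                        # ok | no_amplification | excess_bands
    two_band_cause: Optional[str] = None  # heterozygous | duplication

    @property
    def is_ok(self) -> bool:
        return self.status == "ok"

    @property
    def n_bands(self) -> int:
        return len(self.band_lengths)


def find_binding_sites(primer: str, sequence: str, max_mismatch: int = 2,
                       three_prime_exact_len: int = 3,
                       enc: Optional[np.ndarray] = None
                       ) -> list[tuple[int, str]]:
    """All (start position, strand) where the primer can prime.

    ``start`` is the leftmost base of the matched window on the plus
    strand for both orientations.  For a ``-`` site the primer anneals to
    the plus strand's reverse complement, so its 3' terminus sits at
    ``start``.  ``enc`` may pass the byte-encoded sequence to avoid
    re-encoding in batch genotyping.
    """
    if len(primer) < three_prime_exact_len:
        raise ValueError("primer shorter than the 3'-exact length")
    L = len(primer)
    if enc is None:
        enc = np.frombuffer(sequence.encode(), dtype=np.uint8)
    sites: set[tuple[int, str]] = set()
    for strand in "+-":
        target = primer if strand == "+" else revcomp(primer)
        cands = _candidate_positions(target, sequence, max_mismatch)
        if not cands:
            continue
        pos = np.asarray(cands, dtype=np.int64)
        tarr = np.frombuffer(target.encode(), dtype=np.uint8)
        win = enc[pos[:, None] + np.arange(L)]
        ok = (win != tarr).sum(axis=1) <= max_mismatch
        t = three_prime_exact_len
        if strand == "+":
            ok &= (win[:, L - t:] == tarr[L - t:]).all(axis=1)
        else:
            ok &= (win[:, :t] == tarr[:t]).all(axis=1)
        for p in pos[ok].tolist():
            sites.add((p, strand))
    return sorted(sites)


def _candidate_positions(pattern: str, text: str,
                         max_mismatch: int) -> list[int]:
    """Pigeonhole candidates: positions where some exact chunk matches."""
    L = len(pattern)
    q = max_mismatch + 1
    bounds = [round(i * L / q) for i in range(q + 1)]
    cands: set[int] = set()
    for i in range(q):
        lo, hi = bounds[i], bounds[i + 1]
        chunk = pattern[lo:hi]
        if not chunk:
            continue
        idx = text.find(chunk)
        while idx >= 0:
            start = idx - lo
            if 0 <= start <= len(text) - L:
                cands.add(start)
            idx = text.find(chunk, idx + 1)
    return sorted(cands)


def predict_amplicons(primer_pair: PrimerPair, chrom: str, sequence: str,
                      config: PipelineConfig, haplotype: int = 1,
                      enc: Optional[np.ndarray] = None) -> list[Amplicon]:
    """Amplicons from every (forward '+', reverse '-') site pair whose
    span lies within the e-PCR product window."""
    fwd_sites = find_binding_sites(primer_pair.forward_seq, sequence,
                                   config.epcr_max_mismatch,
                                   config.epcr_three_prime_exact, enc)
    rev_sites = find_binding_sites(primer_pair.reverse_seq, sequence,
                                   config.epcr_max_mismatch,
                                   config.epcr_three_prime_exact, enc)
    rlen = len(primer_pair.reverse_seq)
    out: list[Amplicon] = []
    for fpos, fstrand in fwd_sites:
        if fstrand != "+":
            continue
        for rpos, rstrand in rev_sites:
            if rstrand != "-":
                continue
            span = rpos + rlen - fpos
            if config.epcr_min_product <= span <= config.epcr_max_product:
                out.append(Amplicon(
                    interval=GenomicInterval(chrom, fpos, rpos + rlen),
                    length=span,
                    haplotype=haplotype,
                ))
    out.sort(key=lambda a: (a.interval.chrom, a.interval.start))
    return out


def merge_bands(lengths: list[float], resolution_bp: float) -> list[float]:
    """Merge lengths closer than the gel resolution to their mean.

    Sorted single-linkage clustering; idempotent and order-independent
    (adjacent cluster means stay >= resolution apart).
    """
    if not lengths:
        return []
    vals = sorted(float(x) for x in lengths)
    clusters: list[list[float]] = [[vals[0]]]
    for v in vals[1:]:
        if v - clusters[-1][-1] < resolution_bp:
            clusters[-1].append(v)
        else:
            clusters.append([v])
    return [sum(c) / len(c) for c in clusters]


_SEED_K = 6


def _panel_sites(primers: list[str], sequence: str, max_mismatch: int,
                 three_prime_exact_len: int) -> list[list[tuple[int, str]]]:
    """Binding sites of many primers on one sequence in a single pass.

    Pigeonhole seeding as in :func:`find_binding_sites`, but the first
    ``_SEED_K`` bases of every chunk of every primer are pooled into one
    k-mer table so the sequence is streamed once; full windows are then
    verified vectorised.  Produces exactly the same sites.
    """
    from .kmer import kmer_codes, encode as kencode

    n = len(sequence)
    enc = np.frombuffer(sequence.encode(), dtype=np.uint8)
    codes, valid = kmer_codes(kencode(sequence), _SEED_K)
    # seed table: code -> list of (primer index, strand, chunk offset)
    seeds: dict[int, list[tuple[int, str, int]]] = {}
    targets: dict[tuple[int, str], np.ndarray] = {}
    q = max_mismatch + 1
    unseeded: set[int] = set()
    for pi, primer in enumerate(primers):
        L = len(primer)
        bounds = [round(i * L / q) for i in range(q + 1)]
        if min(b - a for a, b in zip(bounds, bounds[1:])) < _SEED_K:
            # some chunk is shorter than the seed: pigeonhole via the
            # pooled table would be incomplete; scan this primer directly
            unseeded.add(pi)
            continue
        for strand in "+-":
            target = primer if strand == "+" else revcomp(primer)
            targets[(pi, strand)] = np.frombuffer(target.encode(),
                                                  dtype=np.uint8)
            for i in range(q):
                lo = bounds[i]
                code = 0
                for ch in target[lo:lo + _SEED_K]:
                    code = (code << 2) | "ACGT".index(ch)
                seeds.setdefault(code, []).append((pi, strand, lo))
    if not seeds:
        return [find_binding_sites(p, sequence, max_mismatch,
                                   three_prime_exact_len, enc)
                for p in primers]
    table = np.zeros(4 ** _SEED_K, dtype=bool)
    code_arr = np.fromiter(seeds, dtype=np.int64)
    table[code_arr] = True
    mask = table[np.where(valid, codes, 0)] & valid
    hitpos = np.nonzero(mask)[0]
    hitvals = codes[hitpos]
    order = np.argsort(hitvals, kind="stable")
    hitpos, hitvals = hitpos[order], hitvals[order]

    cand: dict[tuple[int, str], set[int]] = {}
    for code, entries in seeds.items():
        lo_i = np.searchsorted(hitvals, code, side="left")
        hi_i = np.searchsorted(hitvals, code, side="right")
        if lo_i == hi_i:
            continue
        positions = hitpos[lo_i:hi_i]
        for pi, strand, off in entries:
            starts = positions - off
            L = len(primers[pi])
            starts = starts[(starts >= 0) & (starts <= n - L)]
            if starts.size:
                cand.setdefault((pi, strand), set()).update(starts.tolist())

    out: list[list[tuple[int, str]]] = [[] for _ in primers]
    t = three_prime_exact_len
    for (pi, strand), starts in cand.items():
        tarr = targets[(pi, strand)]
        L = tarr.size
        pos = np.fromiter(sorted(starts), dtype=np.int64)
        win = enc[pos[:, None] + np.arange(L)]
        ok = (win != tarr).sum(axis=1) <= max_mismatch
        if strand == "+":
            ok &= (win[:, L - t:] == tarr[L - t:]).all(axis=1)
        else:
            ok &= (win[:, :t] == tarr[:t]).all(axis=1)
        out[pi].extend((int(p), strand) for p in pos[ok])
    for pi in unseeded:
        out[pi] = find_binding_sites(primers[pi], sequence, max_mismatch,
                                     three_prime_exact_len, enc)
    return [sorted(set(sites)) for sites in out]


def genotype_panel(markers: list[Marker], assemblies: list[GenomeAssembly],
                   config: PipelineConfig
                   ) -> dict[tuple[str, str], BandSet]:
    """Band sets of every marker across every accession.

    Same result as calling :func:`genotype_accession` per cell, but each
    haplotype sequence is scanned once for all primers together.
    """
    primers: list[str] = []
    for m in markers:
        primers.append(m.primer_pair.forward_seq)
        primers.append(m.primer_pair.reverse_seq)
    cells: dict[tuple[str, str], BandSet] = {}
    for assembly in assemblies:
        amps: dict[str, list[Amplicon]] = {m.name: [] for m in markers}
        for hap_no, chroms in enumerate(assembly.haplotypes(), start=1):
            for chrom, seq in chroms.items():
                sites = _panel_sites(primers, seq, config.epcr_max_mismatch,
                                     config.epcr_three_prime_exact)
                for mi, marker in enumerate(markers):
                    fwd_sites = sites[2 * mi]
                    rev_sites = sites[2 * mi + 1]
                    rlen = len(marker.primer_pair.reverse_seq)
                    for fpos, fstrand in fwd_sites:
                        if fstrand != "+":
                            continue
                        for rpos, rstrand in rev_sites:
                            if rstrand != "-":
                                continue
                            span = rpos + rlen - fpos
                            if config.epcr_min_product <= span <= \
                                    config.epcr_max_product:
                                amps[marker.name].append(Amplicon(
                                    GenomicInterval(chrom, fpos,
                                                    rpos + rlen),
                                    span, hap_no))
        for marker in markers:
            amplicons = sorted(amps[marker.name],
                               key=lambda a: (a.interval.chrom,
                                              a.interval.start))
            cells[(marker.name, assembly.accession_id)] = \
                _bandset_from_amplicons(assembly.accession_id, amplicons,
                                        config)
    return cells


def _bandset_from_amplicons(accession_id: str, amplicons: list[Amplicon],
                            config: PipelineConfig) -> BandSet:
    bands = merge_bands([a.length for a in amplicons],
                        config.gel_resolution_bp)
    if not bands:
        status = "no_amplification"
    elif len(bands) > 2:
        status = "excess_bands"
    else:
        status = "ok"
    cause = None
    if len(bands) == 2 and amplicons:
        haps = {a.haplotype for a in amplicons}
        per_hap_max = max(
            sum(1 for a in amplicons if a.haplotype == h) for h in haps)
        if len(haps) == 2 and per_hap_max == 1:
            cause = "heterozygous"
        elif per_hap_max > 1:
            cause = "duplication"
    return BandSet(accession_id=accession_id, band_lengths=bands,
                   raw_amplicons=amplicons, status=status,
                   two_band_cause=cause)


def genotype_accession(marker: Marker, assembly: GenomeAssembly,
                       config: PipelineConfig,
                       enc_cache: Optional[dict] = None) -> BandSet:
    """Predicted band pattern of one accession (1 or 2 haplotypes)."""
    amplicons: list[Amplicon] = []
    for hap_no, chroms in enumerate(assembly.haplotypes(), start=1):
        for chrom, seq in chroms.items():
            enc = None
            if enc_cache is not None:
                key = (assembly.accession_id, hap_no, chrom)
                enc = enc_cache.get(key)
                if enc is None:
                    enc = np.frombuffer(seq.encode(), dtype=np.uint8)
                    enc_cache[key] = enc
            amplicons.extend(predict_amplicons(
                marker.primer_pair, chrom, seq, config, haplotype=hap_no,
                enc=enc))
    bands = merge_bands([a.length for a in amplicons],
                        config.gel_resolution_bp)
    if not bands:
        status = "no_amplification"
    elif len(bands) > 2:
        status = "excess_bands"
    else:
        status = "ok"
    cause = None
    if len(bands) == 2:
        haps = {a.haplotype for a in amplicons}
        per_hap_max = max(
            sum(1 for a in amplicons if a.haplotype == h) for h in haps)
        if len(haps) == 2 and per_hap_max == 1:
            cause = "heterozygous"
        elif per_hap_max > 1:
            cause = "duplication"
    return BandSet(
        accession_id=assembly.accession_id,
        band_lengths=bands,
        raw_amplicons=amplicons,
        status=status,
        two_band_cause=cause,
    )
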