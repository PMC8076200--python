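"""Sequence and table I/O plus the coordinate/metadata model.

All positional arithmetic in the package is 0-based half-open; every
user-facing table reports 1-based inclusive coordinates (genome-browser
convention).  Genomes are multi-FASTA, one file per accession; a
heterozygous accession carries a second haplotype whose records are marked
with a ``haplotype=2`` token in the FASTA description.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GROUP_LABELS = ("cultivar_indica", "cultivar_japonica", "wild", "other")

IUPAC = set("ACGTRYSWKMBDHVN")

_RC = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class FastaParseError(ValueError):
    pass


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval; ``start == end`` marks a zero-length
    locus (used for pure-insertion sites)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        return self.end

    @classmethod
    def from_1based(cls, chrom: str, start1: int, end1: int,
                    strand: str = "+") -> "GenomicInterval":
        return cls(chrom, start1 - 1, end1, strand)


@dataclass
class GenomeAssembly:
    """Named set of chromosome sequences with accession metadata.

    ``chromosomes`` maps chromosome name -> upper-case sequence.
    ``haplotype2``, when present, holds the same chromosome names for a
    heterozygous accession.  ``softmask`` holds per-chromosome boolean
    arrays flagging bases that were lower-case in the source FASTA.
    """

    accession_id: str
    species: str = ""
    group_label: str = "other"
    chromosomes: dict[str, str] = field(default_factory=dict)
    haplotype2: Optional[dict[str, str]] = None
    softmask: Optional[dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.group_label not in GROUP_LABELS:
            raise ValueError(f"unknown group_label {self.group_label!r}")
        if self.haplotype2 is not None:
            if set(self.haplotype2) != set(self.chromosomes):
                raise ValueError(
                    f"{self.accession_id}: haplotype2 chromosome names differ "
                    f"from haplotype 1")

    @property
    def is_cultivar(self) -> bool:
        return self.group_label.startswith("cultivar")

    def haplotypes(self) -> list[dict[str, str]]:
        out = [self.chromosomes]
        if self.haplotype2 is not None:
            out.append(self.haplotype2)
        return out

    def chrom_names(self) -> list[str]:
        return list(self.chromosomes)

    def mask_for(self, chrom: str) -> Optional[np.ndarray]:
        if self.softmask is None:
            return None
        return self.softmask.get(chrom)


def _open_maybe_gzip(path: Path) -> io.TextIOBase:
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_fasta(path: str | Path, accession_id: Optional[str] = None,
               species: str = "", group_label: str = "other") -> GenomeAssembly:
    """Read a (possibly gzipped) multi-FASTA into a :class:`GenomeAssembly`.

    Lower-case bases are preserved as a soft-mask bit per position and the
    sequence is upper-cased.  Records whose description carries a
    ``haplotype=2`` token populate the second haplotype.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    chroms: dict[str, str] = {}
    hap2: dict[str, str] = {}
    softmask: dict[str, np.ndarray] = {}
    any_mask = False
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            name = record.id
            is_hap2 = "haplotype=2" in record.description.split()
            raw = str(record.seq)
            upper = raw.upper()
            bad = set(upper) - IUPAC
            if bad:
                offset = next(i for i, c in enumerate(upper) if c in bad)
                raise FastaParseError(
                    f"{path}: record {name!r} has non-IUPAC character "
                    f"{upper[offset]!r} at offset {offset}")
            target = hap2 if is_hap2 else chroms
            if name in target:
                raise FastaParseError(
                    f"{path}: duplicate record name {name!r}")
            target[name] = upper
            if not is_hap2:
                mask = np.frombuffer(raw.encode(), dtype=np.uint8) >= ord("a")
                softmask[name] = mask
                any_mask = any_mask or bool(mask.any())
    if not chroms:
        raise FastaParseError(f"{path}: no FASTA records")
    return GenomeAssembly(
        accession_id=accession_id or path.stem.replace(".fa", ""),
        species=species,
        group_label=group_label,
        chromosomes=chroms,
        haplotype2=hap2 or None,
        softmask=softmask if any_mask else None,
    )


def write_fasta(assembly: GenomeAssembly, path: str | Path,
                line_width: int = 80) -> None:
    """Write an assembly as multi-FASTA, restoring soft-mask as lower case."""
    records = []
    for name, seq in assembly.chromosomes.items():
        mask = assembly.mask_for(name)
        if mask is not None and mask.any():
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            arr[mask] += 32  # to lower case
            seq = arr.tobytes().decode()
        records.append(SeqRecord(Seq(seq), id=name, description=""))
    if assembly.haplotype2 is not None:
        for name, seq in assembly.haplotype2.items():
            records.append(SeqRecord(Seq(seq), id=name,
                                     description="haplotype=2"))
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=line_width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# marker tables
# ---------------------------------------------------------------------------

MARKER_TABLE_COLUMNS = [
    "name", "chrom", "pos_1based", "tier", "gap_bp",
    "block_start_1based", "block_end_1based",
    "fwd_seq", "rev_seq", "tm_f", "tm_r",
    "amplicon_start_1based", "amplicon_end_1based",
    "product_ref", "products",
]


@dataclass(frozen=True)
class MarkerRecord:
    """Flat, file-oriented view of a designed marker (one TSV row)."""

    name: str
    chrom: str
    pos_1based: int
    tier: str
    gap_bp: int
    block_start_1based: int
    block_end_1based: int
    fwd_seq: str
    rev_seq: str
    tm_f: float
    tm_r: float
    amplicon_start_1based: int
    amplicon_end_1based: int
    product_ref: int
    products: str  # "member=len;member=len;..."


def write_marker_table(records: list[MarkerRecord], path: str | Path,
                       allow_empty: bool = False) -> None:
    if not records and not allow_empty:
        raise ValueError("refusing to write an empty marker table "
                         "(pass allow_empty=True)")
    with open(path, "w") as out:
        out.write("\t".join(MARKER_TABLE_COLUMNS) + "\n")
        for r in records:
            out.write("\t".join(str(getattr(r, c)) for c in
                                MARKER_TABLE_COLUMNS) + "\n")


def read_marker_table(path: str | Path) -> list[MarkerRecord]:
    records = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != MARKER_TABLE_COLUMNS:
            raise ValueError(f"{path}: unexpected marker table header")
        for line in handle:
            vals = line.rstrip("\n").split("\t")
            kw = dict(zip(MARKER_TABLE_COLUMNS, vals))
            for key in ("pos_1based", "gap_bp", "block_start_1based",
                        "block_end_1based", "amplicon_start_1based",
                        "amplicon_end_1based", "product_ref"):
                kw[key] = int(kw[key])
            for key in ("tm_f", "tm_r"):
                kw[key] = float(kw[key])
            records.append(MarkerRecord(**kw))
    return records


def write_bed(records: list[MarkerRecord], path: str | Path,
              allow_empty: bool = False) -> None:
    """BED of the amplified reference interval (0-based half-open)."""
    if not records and not allow_empty:
        raise ValueError("refusing to write an empty BED "
                         "(pass allow_empty=True)")
    with open(path, "w") as out:
        for r in records:
            out.write(f"{r.chrom}\t{r.amplicon_start_1based - 1}\t"
                      f"{r.amplicon_end_1based}\t{r.name}\n")
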