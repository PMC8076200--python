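"""Synthetic genome panels with full ground truth.

The generator emulates the statistical structure a cultivated-vs-wild
diploid panel presents to the marker pipeline: a random ancestor with a
planted centromere-like tandem repeat array per chromosome, species-level
divergence (SNPs, 1-19-bp small InDels, 20-150-bp large InDels, occasional
repeat-element insertions), shallower accession-level divergence within a
species, heterozygous accessions whose second haplotype is a further
mutated copy of the first, and cultivar-branch diagnostic InDels planted
at ~1-Mb spacing so that marker recovery can be scored against truth.
Backcross progeny are simulated by Poisson recombination in ancestor
coordinates.

Every edit is recorded relative to its source genome; applying the edit
list reproduces the derived genome byte-for-byte, and coordinate maps
composed from the edit lists translate ancestor positions into any
accession (the acceptance oracle).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .seq_io import GenomeAssembly

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


# ---------------------------------------------------------------------------
# mutation model and edits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationModel:
    """Per-bp event probabilities for one branch of the panel tree."""

    snp_rate: float = 0.005
    small_indel_rate: float = 5e-4      # lengths 1-19, geometric
    large_indel_rate: float = 2e-5      # lengths uniform on [20, 150]
    repeat_insertion_rate: float = 0.0  # copies of a library element
    small_indel_geom_p: float = 0.3
    large_indel_range: tuple[int, int] = (20, 150)

    def __post_init__(self) -> None:
        for name in ("snp_rate", "small_indel_rate", "large_indel_rate",
                     "repeat_insertion_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 0.05:
                raise ValueError(f"{name} outside [0, 0.05]")

    def scaled(self, factor: float) -> "MutationModel":
        return replace(self,
                       snp_rate=min(0.05, self.snp_rate * factor),
                       small_indel_rate=min(0.05,
                                            self.small_indel_rate * factor),
                       large_indel_rate=min(0.05,
                                            self.large_indel_rate * factor),
                       repeat_insertion_rate=min(
                           0.05, self.repeat_insertion_rate * factor))


def heterozygosity_model(h: float) -> MutationModel:
    """Haplotype-2 divergence model for an accession with heterozygosity
    scale ``h`` (per-bp SNP rate; indel rates scaled down accordingly)."""
    return MutationModel(snp_rate=min(0.05, h),
                         small_indel_rate=min(0.05, h / 10),
                         large_indel_rate=min(0.05, h / 50),
                         repeat_insertion_rate=0.0)


@dataclass(frozen=True)
class Edit:
    """One mutation in source-genome coordinates.

    ``ref`` is the replaced source substring (empty for insertions), and
    ``alt`` the replacement (empty for deletions, placed before ``pos``).
    """

    pos: int
    ref: str
    alt: str
    kind: str  # snp | small_indel | large_indel | repeat | diagnostic

    @property
    def end(self) -> int:
        return self.pos + len(self.ref)

    @property
    def delta(self) -> int:
        return len(self.alt) - len(self.ref)


def apply_edits(seq: str, edits: Sequence[Edit]) -> str:
    """Apply non-overlapping, position-sorted edits to ``seq``."""
    parts: list[str] = []
    cur = 0
    for e in edits:
        if e.pos < cur:
            raise ValueError("edits overlap or are unsorted")
        if seq[e.pos:e.end] != e.ref:
            raise ValueError(f"edit ref mismatch at {e.pos}")
        parts.append(seq[cur:e.pos])
        parts.append(e.alt)
        cur = e.end
    parts.append(seq[cur:])
    return "".join(parts)


class CoordinateMap:
    """Source -> derived coordinate translation for one edit list.

    Only length-changing edits shift coordinates, so substitutions are
    dropped on construction.
    """

    def __init__(self, edits: Sequence[Edit]):
        edits = [e for e in edits if e.delta != 0]
        self._starts = np.array([e.pos for e in edits], dtype=np.int64)
        self._ends = np.array([e.end for e in edits], dtype=np.int64)
        deltas = np.array([e.delta for e in edits], dtype=np.int64)
        self._cum = np.concatenate(([0], np.cumsum(deltas)))

    def map(self, pos: int) -> int:
        i = int(np.searchsorted(self._ends, pos, side="right"))
        if i < self._starts.size and self._starts[i] < pos:
            pos = int(self._starts[i])  # inside a deleted span
        return int(pos + self._cum[i])


def draw_edits(seq: str, model: MutationModel, rng: np.random.Generator,
               planted: Sequence[Edit] = ()) -> list[Edit]:
    """Independent per-position edits; overlaps resolved in favour of
    planted events, then first-come by position.

    Substitutions never shift coordinates, so only indel-class events go
    through the overlap sweep; SNP positions are then filtered against
    the kept indel spans vectorised.
    """
    L = len(seq)
    events: list[Edit] = []
    # small indels
    n_small = rng.binomial(L, model.small_indel_rate) \
        if model.small_indel_rate > 0 else 0
    for p in np.unique(rng.integers(0, L, n_small)).tolist() if n_small else []:
        ln = int(min(19, rng.geometric(model.small_indel_geom_p)))
        events.append(_indel(seq, p, ln, rng, "small_indel"))
    # large indels
    n_large = rng.binomial(L, model.large_indel_rate) \
        if model.large_indel_rate > 0 else 0
    lo, hi = model.large_indel_range
    for p in np.unique(rng.integers(0, L, n_large)).tolist() if n_large else []:
        ln = int(rng.integers(lo, hi + 1))
        events.append(_indel(seq, p, ln, rng, "large_indel"))
    # repeat-element insertions
    n_rep = rng.binomial(L, model.repeat_insertion_rate) \
        if model.repeat_insertion_rate > 0 else 0
    if n_rep:
        unit = random_sequence(rng, 300)
        for p in np.unique(rng.integers(0, L, n_rep)).tolist():
            copies = int(rng.integers(2, 5))
            events.append(Edit(p, "", unit * copies, "repeat"))
    kept = resolve_overlaps(events, planted)

    # SNPs, excluded from kept indel footprints (vectorised filter)
    n_snp = rng.binomial(L, model.snp_rate) if model.snp_rate > 0 else 0
    if n_snp:
        pos = np.unique(rng.integers(0, L, n_snp))
        shift = rng.integers(1, 4, pos.size)
        if kept:
            starts = np.array([e.pos for e in kept], dtype=np.int64)
            ends = np.array([e.end for e in kept], dtype=np.int64)
            # free iff strictly between the previous end and the next start
            i = np.searchsorted(starts, pos, side="right")
            prev_end = np.where(i > 0, ends[np.maximum(i - 1, 0)], -1)
            next_start = np.where(i < starts.size,
                                  starts[np.minimum(i, starts.size - 1)], L + 2)
            free = (pos > prev_end) & (pos < next_start)
            pos, shift = pos[free], shift[free]
        snps: list[Edit] = []
        base_index = {b: i for i, b in enumerate(_BASE_STR)}
        for p, sh in zip(pos.tolist(), shift.tolist()):
            ref = seq[p]
            bi = base_index.get(ref)
            if bi is None:
                continue
            snps.append(Edit(p, ref, _BASE_STR[(bi + sh) % 4], "snp"))
        kept = list(_merge_sorted(kept, snps))
    return kept


def _merge_sorted(a: list[Edit], b: list[Edit]) -> list[Edit]:
    out: list[Edit] = []
    i = j = 0
    while i < len(a) and j < len(b):
        if a[i].pos <= b[j].pos:
            out.append(a[i])
            i += 1
        else:
            out.append(b[j])
            j += 1
    out.extend(a[i:])
    out.extend(b[j:])
    return out


def _indel(seq: str, p: int, length: int, rng: np.random.Generator,
           kind: str) -> Edit:
    if rng.random() < 0.5 and p + length <= len(seq):
        return Edit(p, seq[p:p + length], "", kind)  # deletion
    return Edit(p, "", random_sequence(rng, length), kind)  # insertion


def resolve_overlaps(events: list[Edit],
                     planted: Sequence[Edit] = ()) -> list[Edit]:
    """Drop events that touch a planted event or a previously kept one."""
    import bisect as _bisect

    kept = sorted(planted, key=lambda e: e.pos)
    for i in range(1, len(kept)):
        if kept[i].pos <= kept[i - 1].end:
            raise ValueError("planted events overlap")
    bstarts = [e.pos for e in kept]
    bends = [e.end for e in kept]
    background: list[Edit] = []
    last_end = -2
    for e in sorted(events, key=lambda e: (e.pos, e.end)):
        if e.pos <= last_end + 1:
            continue
        if bstarts:
            j = _bisect.bisect_right(bstarts, e.end + 1)
            if j > 0 and bends[j - 1] >= e.pos - 1:
                continue  # touches a planted event
        background.append(e)
        last_end = e.end
    return _merge_sorted(kept, background)


def evolve_genome(chroms: dict[str, str], model: MutationModel,
                  rng: np.random.Generator,
                  planted: Optional[dict[str, list[Edit]]] = None
                  ) -> tuple[dict[str, str], dict[str, list[Edit]]]:
    """Mutate every chromosome; returns the derived chromosome set and the
    per-chromosome edit lists in source coordinates."""
    out: dict[str, str] = {}
    edits: dict[str, list[Edit]] = {}
    for name, seq in chroms.items():
        ev = draw_edits(seq, model, rng,
                        planted.get(name, []) if planted else [])
        out[name] = apply_edits(seq, ev)
        edits[name] = ev
    return out, edits


# ---------------------------------------------------------------------------
# species panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelConfig:
    n_chromosomes: int = 2
    chrom_length: int = 3_000_000
    n_wild_species: int = 3
    accessions_per_species: int = 3
    species_model: MutationModel = MutationModel(
        snp_rate=0.005, small_indel_rate=5e-4, large_indel_rate=2e-5,
        repeat_insertion_rate=1e-7)
    accession_model: MutationModel = MutationModel(
        snp_rate=5e-4, small_indel_rate=5e-5, large_indel_rate=2e-6,
        repeat_insertion_rate=0.0)
    het_perennial: float = 0.05   # last wild species: outcrossing perennial
    het_background: float = 0.002
    het_cultivar: float = 0.0
    diagnostic_per_mb: float = 1.0
    diagnostic_len_range: tuple[int, int] = (30, 120)
    diagnostic_offset_range: tuple[int, int] = (3_000, 25_000)
    repeat_array_len: int = 50_000
    repeat_unit_len: int = 500


@dataclass(frozen=True)
class DiagnosticEvent:
    """A cultivar-branch InDel planted for truth-based recovery scoring."""

    chrom: str
    ancestor_pos: int
    length: int
    kind: str          # deletion | insertion (on the cultivar branch)
    ref_pos: int       # reference start of the event locus
    in_repeat_context: bool


@dataclass
class PanelTruth:
    ancestor: dict[str, str]
    species_edits: dict[str, dict[str, list[Edit]]]
    accession_edits: dict[str, dict[str, list[Edit]]]
    het_edits: dict[str, dict[str, list[Edit]]]
    diagnostic_events: list[DiagnosticEvent]
    heterozygosity: dict[str, float]
    species_of: dict[str, str]
    repeat_arrays: dict[str, tuple[int, int]]  # ancestor coords per chrom


@dataclass
class Panel:
    assemblies: list[GenomeAssembly]  # reference first
    truth: PanelTruth

    @property
    def reference(self) -> GenomeAssembly:
        return self.assemblies[0]

    @property
    def others(self) -> list[GenomeAssembly]:
        return self.assemblies[1:]

    def assembly(self, accession_id: str) -> GenomeAssembly:
        for a in self.assemblies:
            if a.accession_id == accession_id:
                return a
        raise KeyError(accession_id)

    def map_ancestor(self, accession_id: str, chrom: str, pos: int) -> int:
        """Translate an ancestor coordinate into accession coordinates."""
        t = self.truth
        species = t.species_of[accession_id]
        sp_map = CoordinateMap(t.species_edits[species][chrom])
        ac_map = CoordinateMap(t.accession_edits[accession_id][chrom])
        return ac_map.map(sp_map.map(pos))


def make_species_panel(config: PanelConfig = PanelConfig(),
                       seed: int = 0) -> Panel:
    """Generate the default cultivated-plus-wild panel with truth.

    Layout: one cultivar species carrying two inbred accessions (the
    reference plus a second cultivar) and ``n_wild_species`` wild species
    with ``accessions_per_species`` accessions each; the last wild species
    is perennial-like with elevated heterozygosity.
    """
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{c + 1:02d}" for c in range(config.n_chromosomes)]
    ancestor: dict[str, str] = {}
    repeat_arrays: dict[str, tuple[int, int]] = {}
    for name in chrom_names:
        unit = random_sequence(rng, config.repeat_unit_len)
        n_copies = config.repeat_array_len // config.repeat_unit_len
        array = unit * n_copies
        flank = (config.chrom_length - len(array)) // 2
        left = random_sequence(rng, flank)
        right = random_sequence(rng,
                                config.chrom_length - flank - len(array))
        ancestor[name] = left + array + right
        repeat_arrays[name] = (flank, flank + len(array))

    # plant cultivar-branch diagnostic InDels near each ~1-Mb anchor
    diag_planted: dict[str, list[Edit]] = {c: [] for c in chrom_names}
    diag_raw: list[tuple[str, int, int, str]] = []
    lo_off, hi_off = config.diagnostic_offset_range
    lo_len, hi_len = config.diagnostic_len_range
    for name in chrom_names:
        L = len(ancestor[name])
        n_anchors = max(1, int(L // 1_000_000 * config.diagnostic_per_mb))
        for a in range(n_anchors):
            anchor = int(a * 1_000_000 / config.diagnostic_per_mb)
            pos = anchor + int(rng.integers(lo_off, hi_off))
            if pos + hi_len >= L:
                continue
            length = int(rng.integers(lo_len, hi_len + 1))
            if rng.random() < 0.5:
                edit = Edit(pos, ancestor[name][pos:pos + length], "",
                            "diagnostic")
                diag_raw.append((name, pos, length, "deletion"))
            else:
                edit = Edit(pos, "", random_sequence(rng, length),
                            "diagnostic")
                diag_raw.append((name, pos, length, "insertion"))
            diag_planted[name].append(edit)

    # species genomes
    species_names = ["Cultivar"] + \
        [f"Wild{chr(ord('A') + i)}" for i in range(config.n_wild_species)]
    species_genomes: dict[str, dict[str, str]] = {}
    species_edits: dict[str, dict[str, list[Edit]]] = {}
    for sp in species_names:
        planted = diag_planted if sp == "Cultivar" else None
        genome, edits = evolve_genome(ancestor, config.species_model, rng,
                                      planted)
        species_genomes[sp] = genome
        species_edits[sp] = edits

    # accessions
    perennial = species_names[-1]
    assemblies: list[GenomeAssembly] = []
    accession_edits: dict[str, dict[str, list[Edit]]] = {}
    het_edits: dict[str, dict[str, list[Edit]]] = {}
    heterozygosity: dict[str, float] = {}
    species_of: dict[str, str] = {}

    def add_accession(acc_id: str, sp: str, group: str, h: float) -> None:
        genome, edits = evolve_genome(species_genomes[sp],
                                      config.accession_model, rng)
        accession_edits[acc_id] = edits
        hap2 = None
        het_edits[acc_id] = {c: [] for c in genome}
        if h > 0:
            hap2, h_edits = evolve_genome(genome, heterozygosity_model(h),
                                          rng)
            het_edits[acc_id] = h_edits
        heterozygosity[acc_id] = h
        species_of[acc_id] = sp
        assemblies.append(GenomeAssembly(
            accession_id=acc_id, species=sp, group_label=group,
            chromosomes=genome, haplotype2=hap2))

    add_accession("Cult_japonica", "Cultivar", "cultivar_japonica",
                  config.het_cultivar)
    add_accession("Cult_indica", "Cultivar", "cultivar_indica",
                  config.het_cultivar)
    for sp in species_names[1:]:
        h = config.het_perennial if sp == perennial else \
            config.het_background
        for i in range(config.accessions_per_species):
            add_accession(f"{sp}_{i + 1}", sp, "wild", h)

    # reference coordinates of the planted events
    ref_id = assemblies[0].accession_id
    diagnostics: list[DiagnosticEvent] = []
    for chrom, pos, length, kind in diag_raw:
        sp_map = CoordinateMap(species_edits["Cultivar"][chrom])
        ac_map = CoordinateMap(accession_edits[ref_id][chrom])
        ref_pos = ac_map.map(sp_map.map(pos))
        if kind == "insertion":
            # map(pos) lands after the inserted sequence; report the
            # locus start on the reference
            ref_pos -= length
        rs, re = repeat_arrays[chrom]
        in_repeat = rs - 1000 <= pos <= re + 1000
        diagnostics.append(DiagnosticEvent(chrom, pos, length, kind,
                                           ref_pos, in_repeat))

    truth = PanelTruth(
        ancestor=ancestor,
        species_edits=species_edits,
        accession_edits=accession_edits,
        het_edits=het_edits,
        diagnostic_events=diagnostics,
        heterozygosity=heterozygosity,
        species_of=species_of,
        repeat_arrays=repeat_arrays,
    )
    return Panel(assemblies=assemblies, truth=truth)


# ---------------------------------------------------------------------------
# crosses
# ---------------------------------------------------------------------------

Segment = tuple[int, int, str]  # ancestor coords, origin 'R' or 'D'


@dataclass
class Progeny:
    generation: str  # F1, BC1F1, BC2F1, ...
    assembly: Optional[GenomeAssembly]
    donor_segments_ref: dict[str, list[tuple[int, int]]]  # ref coords
    donor_fraction: float
    donor_segments_ancestor: dict[str, list[tuple[int, int]]]


def _slice_segments(segs: list[Segment], lo: int, hi: int) -> list[Segment]:
    out = []
    for s, e, o in segs:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 < e2:
            out.append((s2, e2, o))
    return out


def _merge_segments(segs: list[Segment]) -> list[Segment]:
    out: list[Segment] = []
    for s, e, o in segs:
        if out and out[-1][2] == o and out[-1][1] == s:
            out[-1] = (out[-1][0], e, o)
        else:
            out.append((s, e, o))
    return out


def _gamete(hap_a: list[Segment], hap_b: list[Segment], L: int,
            mean_crossovers: float, rng: np.random.Generator
            ) -> list[Segment]:
    n_cx = int(rng.poisson(mean_crossovers))
    cuts = sorted(int(x) for x in rng.integers(1, L, n_cx)) if n_cx else []
    bounds = [0] + cuts + [L]
    pick = int(rng.integers(0, 2))
    out: list[Segment] = []
    for i in range(len(bounds) - 1):
        src = hap_a if (pick + i) % 2 == 0 else hap_b
        out.extend(_slice_segments(src, bounds[i], bounds[i + 1]))
    return _merge_segments(out)


def simulate_cross(panel: Panel, recurrent_id: str, donor_id: str,
                   n_backcrosses: int = 0,
                   crossovers_per_chrom_mean: float = 2.0,
                   seed: int = 0, build_sequences: bool = True) -> Progeny:
    """F1 (``n_backcrosses=0``) or BC_nF1 progeny of recurrent x donor.

    Recombination happens in ancestor coordinates; each backcross gamete
    gets a Poisson number of crossovers placed uniformly per chromosome.
    Parents contribute haplotype 1.  Truth donor segments are returned in
    both ancestor and recurrent-parent (reference-like) coordinates.
    ``build_sequences=False`` skips assembling the progeny genome when
    only the truth segments are needed.
    """
    rng = np.random.default_rng(seed)
    t = panel.truth
    chroms = list(t.ancestor)
    hap1_segs: dict[str, list[Segment]] = {}
    hap2_segs: dict[str, list[Segment]] = {}
    for chrom in chroms:
        L = len(t.ancestor[chrom])
        hap_r: list[Segment] = [(0, L, "R")]
        hap_d: list[Segment] = [(0, L, "D")]
        hyb = (hap_r, hap_d)  # the F1
        for _ in range(n_backcrosses):
            gam = _gamete(hyb[0], hyb[1], L, crossovers_per_chrom_mean, rng)
            hyb = (hap_r, gam)
        hap1_segs[chrom], hap2_segs[chrom] = hyb

    parent = {"R": panel.assembly(recurrent_id),
              "D": panel.assembly(donor_id)}
    maps = {origin: {c: _compose_map(panel, pid, c) for c in chroms}
            for origin, pid in (("R", recurrent_id), ("D", donor_id))}

    def build(seg_lists: dict[str, list[Segment]]) -> dict[str, str]:
        out = {}
        for chrom in chroms:
            pieces = []
            for s, e, o in seg_lists[chrom]:
                ps, pe = maps[o][chrom](s), maps[o][chrom](e)
                pieces.append(parent[o].chromosomes[chrom][ps:pe])
            out[chrom] = "".join(pieces)
        return out

    gen = "F1" if n_backcrosses == 0 else f"BC{n_backcrosses}F1"
    assembly = None
    if build_sequences:
        assembly = GenomeAssembly(
            accession_id=f"{gen}_{recurrent_id}x{donor_id}_s{seed}",
            species="hybrid", group_label="other",
            chromosomes=build(hap1_segs), haplotype2=build(hap2_segs))

    donor_anc: dict[str, list[tuple[int, int]]] = {}
    donor_ref: dict[str, list[tuple[int, int]]] = {}
    donor_bp = 0
    total_bp = 0
    rmap = maps["R"]
    for chrom in chroms:
        L = len(t.ancestor[chrom])
        total_bp += 2 * L
        anc = [(s, e) for s, e, o in
               hap1_segs[chrom] + hap2_segs[chrom] if o == "D"]
        donor_bp += sum(e - s for s, e in anc)
        donor_anc[chrom] = sorted(anc)
        donor_ref[chrom] = sorted(
            (rmap[chrom](s), rmap[chrom](e)) for s, e in anc)
    return Progeny(
        generation=gen,
        assembly=assembly,
        donor_segments_ref=donor_ref,
        donor_fraction=donor_bp / total_bp,
        donor_segments_ancestor=donor_anc,
    )


def _compose_map(panel: Panel, accession_id: str, chrom: str):
    t = panel.truth
    sp = t.species_of[accession_id]
    m1 = CoordinateMap(t.species_edits[sp][chrom])
    m2 = CoordinateMap(t.accession_edits[accession_id][chrom])
    return lambda p: m2.map(m1.map(p))
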