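# Methods

`indelmark` automates a marker-development strategy for distinguishing a
cultivated genome group from its wild relatives on an ordinary agarose
gel: find insertion/deletion polymorphisms (InDels) large enough to
resolve as PCR product-size differences, design primers in flanks
conserved across the whole panel so every accession amplifies, and score
the resulting band patterns. This note records the models, defaults and
numerical choices behind each stage, and what the simulated panels do and
do not establish.

## Pipeline model

**Bait windows.** Marker discovery is anchored on 30–100-kb reference
windows ("baits") placed near every ~1-Mb position of each chromosome.
Repeat content is measured as the fraction of window positions whose
covering 21-mer occurs more than once genome-wide, or that are
soft-masked/N; a window above `max_repeat_fraction` (default 0.3, a
compromise that tolerates scattered short repeats but rejects transposon
arrays and centromeric tandem repeats) is slid forward in half-window
steps until it passes or the next anchor is reached, in which case the
anchor is dropped. The threshold has no published value; 0.3 was fixed a
priori from the intended behaviour on tandem arrays.

**Orthologous regions.** For every other genome the bait's counterpart is
located by exact 15-mer anchors that are unique both in the bait and in
that genome, chained to the longest strictly co-linear run on one
chromosome and strand (patience LIS, then splitting at adjacent-anchor
gaps above 20 kb). A chain needs at least 10 anchors spanning half the
bait; the hit is the chain span padded by 2 kb, reverse-complemented for
minus-strand hits so all downstream coordinates are bait-forward. A
second chain scoring ≥ 0.8× the best flags the hit as ambiguous.
Absence of a hit is expected and legal — a bait proceeds if at least
`min_ortholog_members` (6) members, bait included, are available.

**Alignment.** Each hit is aligned to the bait with a global affine-gap
model (match +1, mismatch −2, gap −6 − 0.2/bp; the flat-ish extension
keeps a 30-bp indel as one event rather than scattered gaps). The DP is
banded on the diagonal offset; the band always covers the net length
difference, and doubles automatically (up to 4×) when the traceback
touches a band edge. Balanced excursions larger than the band (block
transpositions) raise an error rather than silently truncating when they
pin the path to the edge; in anchored mode such segments essentially do
not occur because alignment runs piecewise between exact anchor blocks,
with equal-length micro-segments short-circuited to the diagonal only
when the observed mismatch count makes the diagonal provably optimal.
The pairwise alignments are projected into reference coordinates (one
column per bait base; insertions stored per member at their anchor
position). The projection is lossless — de-projection reproduces every
member byte-for-byte — and InDels are left-aligned so positions do not
depend on the aligner's internal gap placement.

**InDel screening.** Gap events from all members within a 10-bp merge
radius form one block with per-member allele lengths (reference length
included). A block is kept when its maximum pairwise length difference
reaches `min_gap_bp` (default 20 bp, used inclusively: the discussion of
agarose resolution motivates ≥ 20 rather than > 20, and the predicate is
configurable). Classification against the group labels: tier `full` when
every cultivar/wild pair of present members differs by ≥ 20 bp, `partial`
when at least one pair does; members without an ortholog are excluded
from the "all wild" quantifier rather than failing the block. Per bait at
most two blocks are kept, ranked full > partial, then larger gap, then
longer adjacent conserved flank, then position; selected blocks must be
≥ `product_max` apart so amplicons cannot overlap.

**Primer design.** Candidate primers (18–24 nt) are enumerated in flank
windows within 250 bp of the block where no member has a substitution,
gap or insertion junction — even amplification across the panel is the
point of conserved-flank design. Filters: GC 30–70%, no homopolymer run
of ≥ 5, 3' terminus not inside a homopolymer, nearest-neighbor Tm in
[55, 65] °C for the 55 °C annealing protocol, pair ΔTm ≤ 3 °C, 3'
cross/self complementarity ≤ 4 bp. Tm uses the unified nearest-neighbor
parameter set with the entropic salt correction
(ΔS += 0.368 (N−1) ln[Na⁺]) at 50 mM monovalent salt and 0.25 µM primer
(primer-excess convention for the duplex concentration term). Among pairs
whose product lies in [100, 500] bp for **every** member allele, the pair
minimising |longest-allele product − 300| wins, with a positional
tie-break. Primer uniqueness is exact full-length occurrence counting on
both reference strands; near-matches are left to the in-silico PCR
mismatch model. Markers are named `A` + two-digit chromosome + `P` +
five-digit kb position (nearest-kb rounding of the block start, the
biologically meaningful locus; both published example names are
consistent with floor or nearest).

**In-silico PCR and the gel model.** A primer binds where at most 2
mismatches occur over its length and none in the 3'-terminal 3 bases.
The search is seed-and-verify (pigeonhole over max_mismatch+1 chunks),
proven equivalent to the position-by-position scan in the test suite.
Every forward(+)/reverse(−) site pair spanning 50–2000 bp yields an
amplicon; per accession, amplicons from both haplotypes are pooled and
lengths closer than `gel_resolution_bp` (20 bp, constant over the
2.5–4.0% agarose range — a %-to-resolution curve is out of scope) merge
to their mean. No bands → `no_amplification`; more than two →
`excess_bands`. Two bands are annotated as heterozygous when they come
one-per-haplotype, as duplication when one haplotype yields both; the
"weak site" refinement (sites failing only the overall-mismatch rule)
is not modelled.

**Analytics.** A marker is `failed` when more than 30% of its cells are
bad (the published count of failed markers comes with no stated rule;
the threshold is configurable), otherwise `polymorphic` if any accession
differs from either reference cultivar under the gel model, else
`monomorphic`. Polymorphism counts, validation rate (1 decimal), two-band
frequencies (3 decimals, validated-marker denominator), species-level
common-3/common-2/specific marker sets, and neighbor-gap statistics
follow directly. Progeny calls compare a plant's band set with the
parental sets (`H` = union, `A`/`B` = one parent, `failed` otherwise,
non-evaluable when parents are indistinguishable); introgressed segments
are maximal runs of non-recurrent calls per chromosome, with failed calls
transparent.

## Synthetic panels (what they emulate, what they do not)

The generator builds a random ancestor (two 3-Mb chromosomes by default,
each with a 50-kb centromere-like tandem array), derives one cultivar
species and three wild species at species-level divergence (SNP 0.005/bp,
small 1–19-bp indels 5×10⁻⁴, large 20–150-bp indels 2×10⁻⁵, occasional
repeat-element insertions), then accessions within species at 10× lower
rates — reproducing the pattern that accessions of one species share
most diagnostic InDels. Two inbred cultivar accessions (the reference
plus a second cultivar) and 3 accessions per wild species form the
default panel. Heterozygous accessions carry a second haplotype mutated
from the first at scale *h* (SNP rate *h*, large indels *h*/50); the last
wild species is perennial-like with *h* = 0.05 against a background of
0.002 and inbred cultivars at 0. One cultivar-branch diagnostic InDel
(30–120 bp) is planted per Mb at a controlled offset inside the
prospective bait window, giving every run a known denominator for
recovery scoring. Edits never overlap (rejection with a 1-bp guard), so
truth lists are unambiguous and applying them reproduces each genome
byte-for-byte.

Backcross progeny are simulated in ancestor coordinates: each gamete
receives a Poisson(2) number of crossovers per chromosome placed
uniformly; truth donor segments are reported in reference coordinates via
edit-list coordinate maps. Parents transmit haplotype 1, and progeny
evaluation genotypes the parents in that haplotype-1 view; markers whose
amplicon spans a recombination breakpoint are excluded from exactness
scoring (a chimeric product is genuinely ambiguous).

The simulation omits, deliberately: realistic transposon biology and
nested repeats, assembly gaps and errors, GC-dependent PCR failure,
primer secondary structure, band-intensity effects, and coalescent
demography. Passing the recovery suite therefore shows the pipeline's
internal logic is sound under the stated mutation models — not that real
genome assemblies of comparable divergence would yield the same marker
counts or validation rates.

## Problem sizes and determinism

The default panel (2 × 3 Mb, 11 accessions) was chosen as a desk-scale
stand-in for a 400-Mb 8-species panel: large enough that every stage runs
at realistic per-base densities, small enough that a full pipeline run
takes tens of seconds. Recovery statistics aggregate 20 seeded panels;
the acceptance script uses 5 panels plus 50 truth-only and 4 fully
genotyped crosses. Every stochastic component draws from
`numpy.random.default_rng` seeded explicitly; the pipeline itself is
deterministic, so identical inputs, config and seeds give byte-identical
outputs. `--threads` on the CLI is accepted for interface compatibility
and never affects results.

## Known limitations

* Anchor chaining takes the longest co-linear chain and cannot represent
  inversions or translocations inside a bait; minus-strand hits are
  handled only as a whole.
* The gap-bounded chain split keeps the longest piece, so a bait whose
  ortholog is broken into two distant, equally good pieces keeps one.
* Banded alignment outside anchored mode can return a band-constrained
  (sub-optimal) alignment for balanced excursions that never touch the
  band edge; event positions may then shift slightly, though event
  lengths are preserved in practice.
* `conserved_flank_windows` treats any member difference as
  disqualifying at the default `max_mismatch_columns = 0`; panels of very
  divergent genomes may need the relaxed mode.
* Marker names collide if two selected blocks round to the same kb; the
  later marker is dropped with a warning (not observed at default
  settings).
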