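# Methods

This note documents the models and procedures implemented in cassfinder,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show about
real data.

## Coordinates, identity, alignment

All internal coordinates are 0-based half-open (`Interval`); GFF3 output is
1-based inclusive, converted at a single point in `cassfinder.io`. Pairwise
identity is defined as 100 × matched columns / columns where at least one
sequence has a residue, with terminal-overhang columns excluded and internal
gap columns counted in the denominator; `N` never matches. Published repeat
studies rarely state their alignment-viewer's identity definition, so
identity values computed here can differ from published tables by a few
points; the definition above is fixed, documented and used consistently.

Global and local alignments use Biopython's `PairwiseAligner` with
match +1, mismatch −2, gap open/extend −2 — the megablast-style scoring
commonly used for repeat searches. One exception: indel-signature
alignments for variant splitting use affine gaps (open −10, extend −0.5),
because under the flat scoring a real 30 bp indel can be scattered into many
single-column gaps by an equally optimal alignment, destroying the
signature. This is a numerical necessity, not a biological claim.

## Structural TRIM detection

TRIMs are found by their architecture alone (no coding capacity to detect):
two similar direct repeats (LTRs) of `min_ltr=30` to `max_ltr=500` bp
separated by `min_between=30` to `max_between=2000` bp, with pairwise LTR
identity ≥ `min_ltr_identity=70%`. The bounds on the inter-repeat distance
are interpreted as bounds on the internal-region length.

The algorithm: exact `seed_word=12` k-mer matches between positions at an
admissible distance are grouped per diagonal, chained, and extended
ungapped with an x-drop rule (drop 10, match +1/mismatch −2). A boundary
only moves if the extension's net gain reaches `boundary_margin=3`; without
this margin, a single chance-matching flank base (probability 1/4 per side)
shifts reported boundaries off the true repeat edge. The two copies are
then re-aligned globally for the identity statistic, so small indels
between copies are scored correctly even though seeding is per-diagonal.
Overlapping candidates (≥ 50% of the shorter span shared) are resolved by
highest LTR identity, then longer element, then leftmost start — a
deterministic replacement for the manual inspection such searches
traditionally require. Detection is single-strand; the CLI `detect` command
scans both strands and merges.

TSD (longest identical flank duplication of 4–6 bp), PBS (≤ 2 mismatches to
`TGGTATCAGAGC`, a methionine-tRNA-complementary site common in plant LTR
elements, within 20 nt of the 5′ LTR), PPT (first 10 nt window with ≥ 8
purines within 20 nt of the 3′ LTR) and TG…CA termini are annotated as
evidence. In the default relaxed mode none of them filters a candidate;
`strict` mode turns TSD and TG…CA into filters.

Known limitation: copies diverged by large LTR-internal indels are seeded
on multiple diagonals and may be reported with conservative boundaries;
substitution divergence up to ~10% (LTR identity ~80%) is handled well, as
the acceptance sweeps show.

## Promoter annotation and element classification

The internal control region is scanned in its natural order and anchored:
the 15 nt A-Box (≤ 2 mismatches) anchors the search, the 6 nt IE is only
accepted within 20 nt downstream of it, and the C-Box within 30 nt
downstream of the IE. Anchoring matters: a 6 nt motif at ≤ 2 mismatches
matches random sequence at ~4% per position, so an unanchored scan would
hallucinate boxes in most LTR-sized sequences. The cost is that a sequence
whose A-Box is lost reports no downstream boxes either; in element tallies
such elements are counted under `none`.

C-Box classification assigns a 10-mer to the nearest of the three reference
motifs by Hamming distance, with a cutoff of 2 mismatches (the references
are mutually 1–3 apart, so 2 keeps the classes separable while tolerating
one private substitution); exact ties are `ambiguous`, larger distances
`other`. MotIE is the 4 nt immediately preceding the IE and MotC the 5 nt
immediately preceding the C-Box; the literature describes these spacers only
as lying "between" the boxes, so the upstream-anchored convention is a
documented choice. The default gene layout (A-Box [47,62), IE [66,72),
C-Box [79,89) within a 120 bp gene) leaves exactly those 4 nt and 5+ nt
spacers; A-Box/IE default strings are configurable stand-ins for a standard
plant 5S layout, not ground truth — only the three C-Box motifs are
reference values.

The 5S similarity region of an LTR is the best local alignment against the
5S gene, accepted at score ≥ `min_core_score=40` and aligned length ≥
`min_core_len=40` bp. The threshold separates cleanly at desk scale: a real
~70 bp core scores ≥ 55 even at 10% divergence, while the best chance local
alignment of an unrelated 280 bp LTR against a 120 bp gene stays below 30
under this scoring. The region's midpoint is reported as a fraction of LTR
length. An element is `cassandra` if either LTR yields a region (the 5′
LTR's is primary when both do), else `cassandra_like_trim` if `TATAAA`
occurs at 48 ± 5 nt from the 5′ LTR start (the tolerance absorbs detected
boundary shifts of a few bases), else `other_trim`.

## Families and variants

Families are single-linkage connected components of the graph whose edges
are element pairs with global identity ≥ 70% (inclusive). Single linkage is
deliberate: indel-bearing variants depress mean pairwise identity yet
remain chained into their family through the non-indel regions, matching
how such families are curated in practice. Family statistics report medians
of member lengths (even-sized lists: mean of the two central values) and
*mean* all-pairs identities for full/LTR/internal sequences; whether
published family identities are all-pairs or multiple-alignment values is
generally unstated, so the aggregation is configurable and the all-pairs
choice is documented here.

Variants: each member is aligned to the family reference (longest member,
ties by smallest id); internal gap runs ≥ `min_indel=10` bp, binned at
10 bp of reference position and length, form the member's indel signature;
identical signatures form a variant, the empty signature the base variant.

## Dotplots

A dot at (i, j) means the k = 12 windows at i and j differ at ≤ n = 3
positions; computed by exact counting (k shifted equality layers), matching
a brute-force per-position oracle bit-for-bit. Panel shading is the longest
exact common substring divided by the shorter sequence's length — the
normalisation is a documented choice, as figure legends for such plots
usually leave it implicit. Reverse-strand matching is off by default
(LTR panels compare fixed orientations). Rendering (matplotlib) is optional
and never affects computed results.

## rDNA arrangement from reads

Reads are decomposed into k = 31 k-mers; k-mers with count ≥ `min_count=2`
become graph nodes (singleton noise suppression — harmless on error-free
synthetic reads, essential on real data), edges are (k−1)-overlaps, and
non-branching paths are compressed into unitigs. Unitigs are colored by
exact k-mer hits against the rRNA references (18S, 5.8S, 26S, 5S); the
subgraph within `distance=25` unitig hops of any colored node is extracted
(hop count on the unitig graph is this package's reading of assembly-viewer
node distance, and it is a parameter). The call is **L** when one connected
component carries both a 35S-subunit color and the 5S color, **S** when
5S-colored components carry no 35S color and vice versa, and `ambiguous`
when a color is missing or colors split across more than two components. A
perfect tandem array collapses to a cyclic component whose unitig length
equals the monomer length within k−1; circularity is reported but not
required for an L call, since arrangement is often concludable from
imperfect assemblies.

This in-house unitig graph replaces a two-round assembler pipeline: at desk
scale the assembly's only role is to expose monomer topology, which the
unitig graph captures directly and deterministically.

## The simulator: what it emulates, and what it does not

`cassfinder.simulate` generates: 5S units (120 bp gene with planted boxes +
100–500 bp random spacer; spacer length default 300 bp — no published range
exists for the groups of interest, so this is an arbitrary, configurable
choice); Cassandra elements (default LTR 270 bp and internal 82 bp, the
median values reported for the smaller plant Cassandras; a 70 bp 5S core
slice centred at a configurable LTR fraction with the element's C-Box
variant written in; PBS immediately 3′ of the 5′ LTR and a 10 nt PPT
immediately 5′ of the 3′ LTR; 4–6 bp TSD); Cassandra-like TRIMs (same
architecture, no core, `TATAAA` at LTR offset 48); rDNA arrays (linked:
35S monomer of 18S/5.8S/26S marker blocks, 1.8 kb/160 bp/3.4 kb by
default, with the 5S gene inside the intergenic spacer; separated: two
independent arrays); divergence (independent per-LTR substitutions, C-Box
protected so variant identity is a controlled condition; indels uniform
1–30 bp, motivated by the variant-defining indels seen in real LTRs); and
uniform error-free reads.

Deliberate simplifications: 35S subunits are seeded-random marker blocks,
not real rRNA sequences (sufficient for coloring and topology); no
sequencing errors or quality model; no nested insertions; elements are
planted dispersed (`min_separation=3200`, exceeding the largest admissible
element span) — two close copies share an identical 5S core that forms a
genuine cross-copy direct-repeat pair, the confounder that historically
required manual inspection, and the simulator's study conditions exclude
it by construction. Consequently, passing tests demonstrate correctness of
the algorithms under clean, dispersed, substitution-diverged conditions;
they do not demonstrate robustness to nested or clustered insertions,
sequencing error, or diverged rRNA references.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale problems chosen as the package's
own defaults: detector sweeps over 26 kb genomes with 0–5 planted elements,
oracle comparisons on ≤ 3 kb inputs with a narrowed detector config
(max LTR 150 bp, max internal 400 bp — the exhaustive enumeration is
quadratic in sequence length times LTR length), rDNA datasets with
scaled-down marker blocks (400/80/600 bp) at 20× coverage. Coverage 20× is
used for linkage datasets because with 100 bp reads and k = 31 the
per-k-mer coverage is ~0.7× the nominal read coverage, and the
`min_count=2` cutoff needs comfortable margin to never break the monomer
cycle. Seeds derive from a single run seed through `numpy`'s
`default_rng`; identical config + seed gives byte-identical outputs.
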