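# Methods

This note records the model refasm implements, the numerical and design
choices where the design was genuinely open, and what the synthetic
fixtures do and do not show about real assemblies.

## The assembly model

An assembly is a versioned set of assembly units. Exactly one unit is
*primary* and holds the non-redundant haploid chromosomes plus scaffolds
that are unlocalized (chromosome known, position unknown) or unplaced
(chromosome unknown). Alternate loci live in *alt-loci* units; two
alternates whose placements overlap on the primary chromosome are
different representations of the same region and must live in different
units, so annotation pipelines can treat each unit as internally
non-redundant. Patches live in a single *PATCHES* unit.

All interface coordinates are 1-based inclusive (the AGP convention).
AGP validity is structural: rows tile the object exactly (no holes, no
overlaps), component spans equal object spans, part numbers run
consecutively from 1, contigs contain no gap rows. Validation returns
findings as values rather than raising, so a curator sees every problem
at once; the CLI maps a non-empty report to exit status 1.

Alternate loci have no hard size limit; sizes above 5 Mb (unusually large
for an alternate representation) produce a warning finding, never a
rejection. Gaps of unknown size render as 100 N (the AGP "U" convention).
Orientation tokens `?`, `0`, `na` in input AGP are read as `+` with a
logged warning. Gap types outside {contig, clone, scaffold-break} are
treated as scaffold-break.

## Building from tiling paths

Adjacent components in a tiling path must share a dovetail overlap
(suffix of the left component, prefix of the right). Overlap detection
scans every candidate overlap length from `min_len` (default 20) up to
the shorter component and scores exact column identity under a
substitution-only overlap model; the highest-identity overlap at or above
`min_identity` (default 0.97) wins, longest on ties. The scan is
exhaustive rather than seeded, so it is exact and deterministic; at the
component sizes this package targets (1–20 kb, scaled down from the
10–200 kb of real clones) the vectorised scan costs well under a second.

The switch point is the midpoint (floor) of the longest exact-match run
inside the overlap, leftmost run on ties. Midpoint-of-clean-run is this
package's own policy: it is deterministic, reproducible, and keeps the
switch away from the mismatches that make overlap edges unreliable. Real
curation may choose the base that agrees with mapping or quality data the
model does not carry. Emitted AGP rows abut exactly at switch points, so
every overlap base is represented once — the built object length obeys
Σ component lengths − Σ overlap lengths + Σ gap lengths, and every object
base traces to exactly one component base or gap position (the
provenance map makes this checkable per base).

## Placement and liftover

An alternate (or patch) scaffold is placed on its primary span by
*anchored alignment*. Components shared by both tiling paths are anchors:
the component interval used by both AGPs is identical sequence by
construction, so it aligns exactly, base for base. The first and last
components of the alt path must be anchors — placement is pinned at both
ends, and a scaffold without shared anchors is reported unplaceable and
stays unlocalized/unplaced. Only the inter-anchor segments, where the
haplotypes genuinely differ, are aligned with a sequence aligner: global
affine-gap alignment with match +1, mismatch −1, gap open −5, gap extend
−1 (Biopython's PairwiseAligner). The affine penalty matters: under
unit-cost (Levenshtein) scoring, a multi-kilobase random insert aligns as
hundreds of coincidental one-base matches scattered through the gap,
whereas affine scoring produces the single contiguous indel the
structural difference actually is. Full-matrix DP is used rather than a
banded approximation; at desk-scale segment lengths the saving a band
offers is irrelevant and an exact optimum is easier to reason about.

The resulting placement is a list of gapless blocks, sorted and
non-overlapping on both axes, equal lengths on both axes, stored in a
TSV with a compact block-list column. Placements are canonical forward
orientation: alt scaffolds are built oriented to match the primary
strand, and the parser rejects reverse-orientation records rather than
risk a silently wrong monotone map. Liftover inside a block is exact
offset arithmetic; a query in an indel returns no-map plus both nearest
flanking mapped positions, leaving rounding conventions to the caller.
Liftover is a partial bijection: alt→primary→alt is the identity on
every mappable position.

## Releases

A minor release deep-copies the assembly, increments the patch number,
and adds the new patches to the PATCHES unit. New patches may overlap
primary regions (that is what FIX patches are for) but not other active
patches. The coordinate-stability contract — every primary sequence and
every pre-existing placement byte-identical across a minor release — is
asserted inside `minor_release` itself, not just in tests. Patches are
never dropped by minor releases, so the active set at .pK is the union of
everything introduced at .p1….pK.

The major-release policy is `n_fix ≥ 100 or pct_affected > 1` (the
percentage bound is exclusive: 1.0 does not trigger). "Euchromatic
sequence" is operationalised as non-gap primary-unit bases, and the
percentage is the union of FIX-patch primary spans intersected with
non-gap bases (overlaps counted once), measured on the primary span
rather than patch scaffold length — the primary span is what re-annotation
cost scales with.

At a major release FIX patches are spliced first: each replaced primary
span is swapped for the patch scaffold's aligned span, both in sequence
and in AGP rows (rows are cut at splice boundaries with component
coordinates adjusted, so the new chromosome still rebuilds exactly from
its AGP). The remap table covers preserved segments only, as
(old span, new span, offset) rows; positions inside a replaced span are
deliberately unmappable because that sequence no longer exists. NOVEL
patches are promoted after splicing, so their placements are remapped to
post-splice coordinates; each goes to the first alt-loci unit where it
overlaps no existing member, with a fresh unit created when every
existing one conflicts. A NOVEL patch whose placement reaches into a
FIX-replaced span is a conflict requiring curation, as are overlapping
FIX patches.

Curation issues carry one of seven types — clone-problem, path-problem,
grc-housekeeping, missing-sequence, variation, gap, unknown — and a
resolution release once resolved; the summary counts resolved issues per
type per release.

## Synthetic data

`gen_components` tiles a hidden uniform-random truth sequence with n
clone-like components (defaults: 5 components of 5 kb overlapping 500 bp
— clone geometry scaled down ~10× to keep everything interactive on one
CPU). Overlap columns carry Bernoulli substitution errors (default 1 %,
applied to the downstream component's prefix), emulating discrepancies
between independently sequenced clones.

`gen_variant_region` builds the dual-haplotype fixture: insertion
haplotype A·s_l·U·s_r·B and deletion haplotype A·s_l·s_r·B, where A and B
(5 kb each) are shared anchor components, s_l/s_r are shared 800 bp
spacers carried by the haplotype-specific middle components, and U is a
2 kb uniform-random insert unique to the insertion allele (no 50-mer in
common with the deletion haplotype, checked exhaustively). Each middle
component dovetails 500 bp into each anchor. `gen_patches` draws random
FIX/NOVEL patches as mutated copies (substitutions, optional one indel)
of random primary spans, placed back by alignment — always valid input
for a minor release.

`simulate_reads` draws uniform start positions and per-base substitution
errors (default 100 bp reads, 1 % error), recording each read's truth
position. The read aligner in `evaluate_alt_awareness` is intentionally
minimal: best infix placement by edit distance (edlib), an edit budget of
10 % of read length, deterministic tie-breaking, no mapping quality and
no pairing. A read is alt-specific when its truth span overlaps the
insertion that only the alternate locus carries; correctness means
placing within 3 bp of truth in haplotype coordinates (placements on the
primary are converted through the alt placement's liftover).

What these fixtures do not model: repeats and segmental duplications
(uniform-random sequence makes misplacement *harder* than in a real
genome, so the without-alt misplacement fraction here overstates
unaligned and understates misplaced relative to real data), indel
sequencing errors, paired ends, coverage biases, and production aligner
heuristics. Passing tests therefore demonstrate the *direction* of the
alternate-locus effect and the exactness of the model's bookkeeping
contracts, not quantitative alignment rates for any real genome.

## Problem sizes in the checks

The test suite and `scripts/acceptance.py` run entirely on generated
data: 50 chained minor releases on a 50 kb chromosome for coordinate
stability; 100 release events for cumulativity; ~36 kb splices for
major-release conservation; 100 random tiling paths for the builder;
100 random indel placements (plus the alignment-derived 50 bp insertion
fixture, whose alt 600 → primary 550 mapping is checked against an
independent Gotoh DP oracle) for liftover; and 20 seeds × 500 reads for
the alt-awareness comparison. These sizes were chosen so the full suite
completes in seconds while every contract is still exercised per base.
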