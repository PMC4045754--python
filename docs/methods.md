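# Methods

## The problem

A DNA-barcode reference library is only as useful as its internal
structure allows: queries are assigned to species by sequence
similarity, so identification is reliable exactly where within-species
variation stays clearly below between-species divergence.  This
package audits a curated library of aligned mitochondrial COI barcodes
(the standard 658-bp 5' fragment) for that property, and identifies
query sequences against it.

## Distances

All divergences are Kimura two-parameter (K2P) distances.  With P the
observed proportion of transition differences (A<->G, C<->T) and Q the
proportion of transversion differences over the compared sites,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

Comparison uses *pairwise deletion*: a column enters a pair's tally
only when both sequences carry an unambiguous A/C/G/T there.  Gaps, N
and IUPAC ambiguity codes exclude the column for that pair alone, so
each pair has its own effective length.  Partial ambiguity codes (R,
Y, ...) are excluded like N rather than fractionally matched — the
simplest defensible reading of pairwise deletion; the alternative
would change distances only in libraries with many ambiguous calls.

A distance is *undefined* when the pair shares no unambiguous columns
(no-overlap) or when either logarithm argument is non-positive
(saturation).  Undefined entries are flagged, never silently zeroed,
and are excluded from all summaries with logged counts.  Pairs with
fewer than 100 compared columns are kept but marked low-confidence.
Distances are stored as proportions; report layers print percentages
with two decimals.

## Haplotypes

Haplotype equality is exact full-string identity of the aligned
sequences.  This relation is transitive and row-order independent;
zero K2P distance under pairwise deletion is not transitive (an
ambiguous sequence can sit at distance zero from two distinct
haplotypes), so it is unsuitable as an equivalence.  A consequence:
a sequence containing ambiguity codes is its own haplotype unless
another specimen matches it exactly.

Accumulation curves subsample specimens without replacement in
uniformly random orders (default 1000 permutations, seeded) and report
the mean number of distinct haplotypes among the first n.  At n = N
the curve equals the total haplotype count exactly.

The haplotype-diversity resampling retains at most two specimens per
(species, haplotype) cell so summary statistics reflect haplotype
diversity rather than haplotype frequency.  Retention is deterministic
(lexicographically smallest specimen ids) to keep the pipeline
bit-reproducible; a seeded random mode exists for sensitivity
analysis.

## Divergence classes, diagnostics and the barcode gap

Every unordered specimen pair is intraspecific, congeneric (same
genus, different species) or intergeneric; the three counts always sum
to C(N,2).  Placeholder species ("sp. <code>") are distinct species
and never merged.

Class summaries report mean, median, extremes and the 2.5th/97.5th
percentiles (linear interpolation between order statistics — the exact
convention matters only at small n, and it is stated here because box
plot software varies).  Outliers are values outside the whisker
interval.

Per species, Max-WSD is the maximum distance between conspecific
specimens (undefined for singletons) and Min-BSD the minimum distance
between any member and any heterospecific specimen, minimised at
specimen level.  A species *fails* when Max-WSD >= Min-BSD: its
internal variation reaches another species, so nearest-neighbour
assignment can mislead.  Min-BSD = 0 means a haplotype is shared with
the nearest species.  Singletons are never flagged by this rule (they
have no Max-WSD), which understates risk for under-sampled species —
a known limitation of the diagnostic, not of the implementation.

The barcode gap is assessed after outlier trimming: the largest
intraspecific value at or below the upper whisker against the smallest
interspecific value at or above the lower whisker.  When the trimmed
interval is non-empty the gap "exists" (possibly only imperfectly,
i.e. only after trimming) and the midpoint is suggested as an
assignment threshold; otherwise the configured fallback of 1.5%
applies — the conventional cutoff below which interspecific divergence
is considered exceptionally low.

## Trees, supports, monophyly, problem clades

Trees are built by canonical Saitou–Nei neighbor joining on the K2P
matrix.  Two contracts make results bit-reproducible: among pairs
minimising the Q criterion, the pair whose sorted cluster keys
(smallest contained leaf name) are lexicographically smallest is
joined; and negative branch-length estimates are clamped to zero with
the deficit moved to the sister branch (sum preserved), with clamps
counted.  NJ is consistent on additive matrices: the test suite checks
exact topology recovery and path-length reproduction (<1e-9) on random
additive trees.

The tree is unrooted (trifurcating root representation).  Monophyly is
a bipartition property — a leaf set is monophyletic iff some edge
separates exactly that set — so no outgroup is assumed.  Singletons,
full sets and (n-1)-sets are monophyletic by the pendant-edge
argument.

Bootstrap support resamples alignment columns with replacement,
recomputes the matrix and tree per replicate (default 500 replicates),
and reports for each reference bipartition the percentage of retained
replicates containing it.  Replicate r draws from an independent RNG
stream keyed (seed, r), so supports are independent of replicate order
and of leaf input order.  Replicates that produce undefined distances
are dropped and counted, with denominators adjusted.

Problem clades: flagged species are joined into connected components
when the minimum between-species distance of a pair falls below the
clade threshold (default 1.5%).  For each component the smallest clade
of the tree containing all member specimens is located; the report
lists every species inside that clade (unflagged nested species
included), within-clade per-species Min-BSD range and mean, the
clade's bootstrap support, and its minimum distance to any outside
specimen.  Real studies assemble such clusters by inspecting the tree;
the component-then-smallest-clade construction is this package's
mechanical, reproducible equivalent.

## Query identification

Queries are globally aligned (match +1, mismatch −1, gap open −5, gap
extend −2, free end gaps; configurable) to the library's majority-rule
consensus and projected onto the fixed column frame; uncovered columns
become gaps, which pairwise deletion then ignores.  A query matching
fewer than 100 reference columns is rejected; an optional mode also
tries the reverse complement and keeps the better orientation.  Hits
are ranked by K2P distance (ties broken by specimen id); similarity is
uncorrected percent identity.  Assignment: best distance above the
threshold gives "no-match"; otherwise all species within the threshold
of the best hit are collected — one gives a species call, several give
a species-group call, the honest answer when barcodes cannot separate
close species.

## Synthetic data

The simulator evolves sequences under the Kimura 1980 model — the same
family the K2P estimator inverts, so recovery is unbiased and expected
distances are additive along the lineage tree.  The hierarchy is
root → genus ancestor → species ancestor → specimen, with branch
lengths

    specimen: intraspecific_d / 2
    species:  (congeneric_d − intraspecific_d) / 2
    genus:    (intergeneric_d − congeneric_d) / 2

chosen so the pairwise expectations equal the configured class means
exactly (conspecifics: intraspecific_d; congeners: congeneric_d;
different genera: intergeneric_d).  Defaults mirror a well-sampled
mitochondrial barcode survey: 0.3% / 6.5% / 10% class means, kappa = 4
(a typical mitochondrial transition/transversion ratio), 658-bp
sequences, 43% singleton species.  Engineered haplotype sharing
(probability p_share per congeneric species pair) adds one identical
sequence to each species of the pair, which forces Min-BSD = 0 and a
failure flag on both — ground truth for the diagnostic.

What the simulator does *not* emulate: rate variation across sites and
lineages, indels (the alignment is fixed-width by construction),
coalescent structure within species, uneven specimen counts beyond the
singleton fraction, and base-composition bias.  Passing tests on
synthetic data therefore demonstrate correctness of the computations
under the model's assumptions, not robustness to every property of
real libraries.

## Problem sizes and numerical choices

The default test and acceptance runs use 5 genera × 4 species × 4
specimens (~50–60 specimens after singleton thinning), 658 bp — large
enough that class means recover within ~20% relative error while the
whole audit, bootstrap included, runs in seconds.  At this size the
intraspecific mean rests on only a few dozen pairs, so it is the
noisiest recovered statistic.  Monte-Carlo distance recovery is
checked at 10,000 sites against the delta-method standard error of the
K2P estimator.  Percentiles use linear interpolation; NJ ties and
dedup retention are broken lexicographically; all RNG is
numpy.random.Generator seeded explicitly and recorded in the run log.
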