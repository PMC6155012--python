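# Methods

## Scope and design

`mzatlas` implements the bespoke computations used to separate human
marginal-zone (MZ) from memory B cells across three data arms — suspension
mass cytometry, imaging mass cytometry (IMC), and IgH repertoire
sequencing — together with synthetic-data generators that carry ground
truth, so every recovery claim in the test suite is checked against known
labels rather than visual judgement.

The package is organised as an analysis project: the computation lives in
`src/mzatlas/`, and the numbered scripts under `analysis/` are thin
narrative drivers that run each arm and write tables under `results/`.
The scripts plus the `mzatlas.pipeline` functions (RunConfig,
run_pipeline, per-stage seed derivation, manifests) are the interface; no
shell CLI is shipped.

## Suspension cytometry

Events are arcsinh-transformed (`x -> asinh(x / cofactor)`, cofactor 5,
the mass-cytometry convention), gated to live single CD45+CD3-CD14-CD19+
B cells by sequential threshold gates, and embedded in 2-D on the nine
subset-defining markers (CD10, CD24, CD27, CD38, IgA, IgD, IgM, IgG,
HLA-DR).  The embedding contract is pluggable — any seeded,
neighbourhood-preserving method qualifies; Barnes-Hut t-SNE is the
default and a PCA fast path exists for smoke tests.  No test or reported
number depends on exact embedding coordinates, only on recovery metrics.

Events are then clustered into k nodes (default 100) by k-means on the
two embedding coordinates only, mimicking node-based clustering run on
the embedding; node medians are computed on **all** panel markers,
including markers withheld from the embedding (CD45RB is the canonical
readout: precursor-rich nodes inside the naive region light up in CD45RB
without CD45RB having shaped the embedding).

Nodes are grouped into the twelve subset bubbles by explicit rules over
node medians, evaluated in a fixed priority order (escape clause for
non-B nodes, then plasmablast, GC, transitional, precursor, MZ, IgM-only,
switched subsets, naive; unmatched nodes become "other").  The original
workflow drew bubbles by hand; a rule list is the reproducible
equivalent, and the priority order resolves ties deterministically.
Rule thresholds are midpoints between archetype locations on the
synthetic scale; real data require user-supplied thresholds.

Per-sample profiles for multidimensional scaling concatenate per-subset
marker medians with subset fractions.  MDS is classical (Torgerson)
scaling — deterministic, and exact (stress-1 <= 1e-6) whenever the
profiles actually lie in a 2-D affine subspace — with Kruskal stress-1
reported as sqrt(sum (d_ij - delta_ij)^2 / sum delta_ij^2).  The subset
dendrogram uses Euclidean distance on subset median vectors over all
measured markers with Ward linkage (configurable).

## Bootstrap distinctness test

To ask whether a focal subpopulation (CD45RB+ cells inside the naive
bubble) is phenotypically distinct from its parent population, the test
resamples `n_focal` cells with replacement from the parent B = 10,000
times, records the per-marker median of each resample as the null
distribution, and reports z = (observed focal median − null mean) / null
SD per marker.  Design choices:

- Null SD uses denominator B: the null vector is the complete Monte-Carlo
  distribution, not a sample whose variance needs an unbiased estimator.
- Degenerate nulls (SD 0): z = 0 if the observed median equals the null
  mean, signed infinity otherwise.
- The test is two-sided; the default flag threshold |z| >= 2 is inclusive
  at the boundary.  No multiple-testing correction is applied; the
  marker count is carried in the result so users may correct.
- An empirical p-value (rank of the observed median among the null
  medians, +1 smoothing, two-sided) accompanies the z-score because
  resample medians are distinctly non-normal for small n_focal.
- The parent includes the focal cells by default (the focal subpopulation
  is part of the bubble being resampled); callers can pass a
  focal-excluded parent.
- Resampling is chunked so B x n_focal index matrices stay within tens of
  megabytes at any population size.

The test suite checks the implementation against exhaustive enumeration:
for a 4-event parent and n_focal = 2 all 16 ordered resamples are
enumerated, and the bootstrap mean/SD must agree within 3 Monte-Carlo
standard errors; the type-I flag rate under resampling from the parent
must match the enumerated null exceedance.

## Imaging mass cytometry

The unit of analysis is the pixel; there is no cell segmentation.  Tiles
are stitched at integer offsets (later tile wins on overlap), per-channel
thresholds zero out intensities strictly below threshold, and retained
pixels become rows of an event table with x/y stored as linear-scale
columns (0-based, row-major, origin top-left, x = column, y = row).

Classification is sequential: stage 1 embeds/clusters pixels on all
channels and keeps nodes whose CD19 and CD20 medians clear their
thresholds; stage 2 re-embeds the kept pixels on the nine B-cell markers
(CD10, CD19, CD20, CD24, CD27, CD38, CD45RB, IgM, IgD) and assigns nodes
to subsets with the same rule machinery as the suspension arm (the
class-switched memory rule is CD27+IgM-IgD- since switched isotypes are
not imaged).  Nodes no rule claims are "other" and are excluded from
every mask.  For scalability each stage embeds a random pixel subsample
(default 3,000) and assigns the remaining pixels to the nearest node
centroid in marker space; with the default 512x512 image this keeps the
full pipeline under a minute on one core.

Spatial statistics use the exact Euclidean distance transform measured
from the reference mask boundary (zero inside the reference), matching
"adjacent to" semantics rather than centroid distances.  Held-out-marker
validation reports Spearman rank correlation of subset medians (CD45RB,
CD24 — markers not used for pixel subset designation) between the pixel
and suspension arms.

## Repertoire QC

Read-level stages follow amplicon convention: remove reads with length
< 250 or mean Phred < 20 (mean computed on raw Phred scores, not error
probabilities — simpler and standard); demultiplex by exact 10-nt MID
match (5' assignment, 3' excision when present); match primers ungapped
at the expected offsets with mismatch fraction <= 0.2 (inclusive), mask
the forward-primer region with Ns (length preserved), trim the
reverse-primer region, and infer isotype from the reverse
(constant-region) primer; collapse duplicates on (sequence, MID, forward
primer, reverse primer).  Every stage logs removals by reason and
conserves counts (retained + removed = input).

Sequence-level QC on annotated rearrangements removes non-functional
sequences and those with mismatched 5'/3' MIDs (chimera signature), then
applies the sliding-window chimera rule: remove if any full-length 10-bp
window against the position-aligned germline contains more than five
mismatches (strictly more; trailing windows shorter than 10 are not
evaluated; N positions never count).  Mutation counts exclude N-masked
and junction N-region positions, so frequencies are relative to
germline-templated positions only.  V(D)J assignment itself is out of
scope: annotation is consumed from the input table (generator truth for
synthetic data).

## Clonal grouping

Clones are defined in two steps: partition by V gene, J gene and junction
length (allele suffixes like *01 collapsed to the gene level, since
allele miscalls would otherwise split true clones), then single-linkage
connected components under normalised weighted junction distance < 0.2
(strict).  The distance weights each mismatch by a 5-mer-context
substitution model of somatic hypermutation targeting, symmetrised as the
mean of the two directional weights, and divides by the evaluated
junction length; with uniform weights (the default when no model TSV is
supplied) it reduces exactly to normalised Hamming distance.  N positions
are skipped and excluded from the length.  Distances are computed on the
junction string as stored.

Distance-to-nearest diagnostics report each sequence's minimum distance
within its partition group (singletons are undefined, never zero) and
suggest a threshold at the deepest KDE valley between the two largest
density modes — a diagnostic to sanity-check the default of 0.2, not a
replacement.

Lineages are germline-rooted minimum spanning trees on substitution-count
distances over clone members plus the germline — a parsimony-style
approximation to full maximum-parsimony search, with ties broken toward
higher duplicate count then lexicographic id, and the summed edge weight
reported as the parsimony score.  The test suite verifies tree weight
against an independent MST oracle on clones of <= 6 members.

## Clone-sharing statistics

The clone x (site, isotype) abundance matrix counts unique sequences;
row sums equal clone totals and log10(n + 1) is used only for display.
Column clustering normalises each column to a clone-frequency
distribution, takes manhattan (L1) distances and applies Ward
agglomeration (the Ward.D-on-precomputed-distances convention).

Sharing percentages are directional: the numerator counts subset-A
sequences at site 1 whose clone contains at least one subset-B member at
site 2; the denominator is all subset-A sequences at site 1; both
directions are reported.  Counts are unique-sequence by default with a
duplicate-weighted variant behind a flag.

GC-membership rates count, among clones containing a defining subset in
gut-associated lymphoid tissue (GALT), those with at least one GC member.
The IgA-overlap test builds a per-donor 2x2 table (clone class x
contains-IgA-member), applies the two-sided Fisher exact test
(probability-mass rule), combines donors by Fisher's method
(X^2 = -2 sum ln p_i ~ chi-squared on 2k df; donors with a zero margin
are excluded, not imputed), and reports a pooled-table Fisher exact
alongside, clearly labelled, since the exact per-donor table construction
behind the published combined value is not printed.  The public-sequence
rate is the percentage of unique sequences whose exact nucleotide string
occurs in more than one donor.

## Synthetic data: what it emulates and what it does not

**Cytometry.**  Subset archetypes are location-scale normals truncated at
zero directly on the arcsinh scale (the analysis operates post-transform,
so simulating raw ion counts would add machinery without adding test
power).  Default spread 0.35; eleven cell archetypes over an 18-marker
panel.  The precursor archetype encodes the precursor-vs-naive shift
(higher CD24, IgM, CD45, CD45RB; lower BCMA, HLA-DR, IgD, CD38), and the
innate-like markers CD21/CD180 are high on MZ and precursor but not on
memory subsets, so the precursor-MZ phenotypic affinity emerges in
all-marker clustering for the same reason it does in the tissue biology.
Tissue identity adds a reproducible per-marker location offset (sd 0.1,
seeded by the tissue name) shared by all subsets, which is what makes
biological replicates of one tissue cluster together in MDS.  Not
emulated: spillover/crosstalk between channels, acquisition drift, bead
normalisation residuals, doublets.  Passing tests therefore demonstrate
the pipeline's logic and calibration, not robustness to instrument
artefacts.

**Tissue geometry.**  Default 512x512 px at 1 µm/px with 12 channels:
epithelium band at the top, class-switched memory band directly beneath
it (subepithelial, as switched memory sits in tissue), GC disc deeper in
the tissue with the MZ annulus sharing the GC boundary, plus naive and
T-cell regions.  Zones are disjoint by construction and truth masks are
exact.  A concentric memory ring around the MZ annulus was rejected
because ring symmetry would equalise mean distances to the epithelium and
erase the spatial ordering the geometry is meant to exhibit.  Pixel
values are zone-archetype locations plus gaussian background noise
(sd 0.35, truncated at zero); noise 0 reproduces the locations exactly.
Not emulated: cell-scale texture, partial-volume mixing at zone
boundaries, ablation artefacts.

**Repertoire.**  Clones draw V/J from a bundled toy germline pool (10 V
of 210 nt, 4 J of 30 nt, generated deterministically), a junction length
of 24-57 nt (multiple of 3, starting TGT), and a power-law size (exponent
2.5, max 50).  Members mutate independently from the clone founder (star
topology) at a per-base rate (default 0.02) scaled per clone class, with
optional 5-mer hot-spot multipliers (uniform by default — enough to
exercise weighted distances without full hot-spot fidelity).  Clone
classes emulate the study's biology: blood-resident unmutated naive
clones; GALT MZ-containing clones (rare GC members, never IgA); IgM-only
clones (rare GC and rare IgA members); isotype-faithful class-switched
clones; memory clones home in GALT sites and recirculate through blood.
Chimeras are splices of the called V with a *different* germline V at a
random breakpoint, flagged in truth; separate small fractions are marked
non-functional or MID-inconsistent.  Reads are laid out as
MID + forward primer + sequence + isotype-specific reverse primer + MID,
emitted per duplicate count, with per-read mean Phred drawn from a
two-component quality model.  Not emulated: homopolymer errors,
insertion/deletion SHM, gapped alignments, selection, shared public
clones (so the expected public-sequence rate is exactly zero).

## Numerical choices and degenerate inputs

- All generators and analyses are deterministic given their seed; a
  single global seed expands to per-stage seeds via `SeedSequence`
  spawning so stages can be re-run in isolation.
- Empty subsets yield missing medians, never zero; singleton sequences
  have undefined (NaN) distance-to-nearest; degenerate Fisher tables are
  excluded with a log entry; zero-margin MDS input raises.
- Strict-vs-inclusive boundaries are fixed and tested: length < 250 and
  mean Q < 20 removals are strict, the 0.2 primer error budget is
  inclusive, the clone threshold is strict (< 0.2), the chimera rule is
  strict (> 5 in 10), and the |z| >= 2 flag is inclusive.
- Stitching overlap: later tile wins.  Denoise zeroes strictly-below
  threshold values.
- Problem sizes in tests and drivers (3,000-5,000 events per cytometry
  sample, 4 donors x 500 clones, 512x512 px single image, B = 2,000 for
  repeated calibration runs and 10,000 for single tests) were chosen as
  desk-scale defaults that keep each analysis in seconds to a minute
  while leaving all recovery margins wide.

## Known limitations

- Bubble rules assume the synthetic scale; applying them to real data
  without recalibrated thresholds will misassign subsets.
- The lineage MST is a parsimony approximation; it never infers
  unobserved intermediate nodes, so internal branching on sparse clones
  differs from full maximum-parsimony trees.
- The pooled IgA-overlap Fisher test is a surrogate for the per-donor
  combination when only pooled counts are available; both are reported.
- The distance-to-nearest valley finder needs a genuinely bimodal
  distribution; on tiny or single-clone inputs it returns no suggestion.
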