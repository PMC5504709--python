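# Methods

`domainscope` re-implements, as a reusable library, the computational core of
a targeted chromosome-conformation-capture analysis: a ~2.7-Mb 5C experiment
binned at 30 Kb and a ~750-Kb capture Hi-C (C-TALE-style) experiment binned at
5 Kb, carried from primer/read-level input through matrix normalization to
domain segmentation, compartment annotation and interaction statistics. This
note records the models, the parameters that matter, and the choices made
where the design was genuinely open.

## Data model

All coordinates are 0-based half-open; BED output is written as-is and
1-based formats are converted at the boundary. A `ContactMap` is a dense
symmetric matrix over a fixed-width `BinGrid` with a per-bin validity mask
(True = usable). Masked bins always carry zero rows/columns; masks are
serialized as a sidecar BED of excluded intervals, because a mask is data,
not derived state. Triplet-format matrix files store the upper triangle once
and the reader mirrors it, which both halves file size and makes asymmetric
input unrepresentable.

## 5C design and binning

Forward and reverse 5C primers are placed on alternating restriction
fragments; ligation products are only detectable between a forward and a
reverse primer. Fragments shorter than 100 bp or longer than 50 Kb are
ineligible. The alternation starts with a forward primer and skipped
fragments do not reset the phase — the source protocol does not pin either
choice; with this convention a 185-fragment design yields 93 forward and 92
reverse primers interrogating 8,556 pairs, matching the published design
size. Primers with zero total interactions in any cell type are removed
jointly from all cell types ("dead" detector filtering); totals are per
merged cell type, not per replicate.

Binning assigns each primer pair to the bins of its two fragment midpoints
(a fragment straddling a bin edge is unambiguous under the midpoint rule) and
takes the arithmetic mean — not the sum — of contributing pair counts, so a
bin's value does not scale with primer density. Same-fragment pairs are
excluded. The per-bin-pair contribution count is kept alongside the matrix so
an empty bin pair is distinguishable from a measured zero.

## Read-pair filtering (capture Hi-C)

The filter cascade classifies each read pair with the first matching rule in
a fixed order:

1. **off_target** — either end outside the capture target;
2. **duplicate** — exact (position, strand) of both ends seen before, after
   canonical end ordering (the standard Hi-C dedup identity; first occurrence
   kept);
3. **near_site** — either end within 5 bp (inclusive) of a restriction site;
4. **fragment_length** — either fragment <100 bp or >100 Kb;
5. **same_fragment** — both ends on one fragment (self-ligation);
6. **proximity** — ends closer than 500 bp (dangling ends; 499 bp is removed,
   500 bp retained);
7. **valid** otherwise.

Precedence only affects the label a failing pair receives, never the retained
set — a property the test suite asserts directly. Valid pairs are grouped by
fragment pair and binned by fragment midpoints; the bin value is the mean
read count over contributing fragment pairs, symmetric with the 5C rule.
Untouched bins are masked.

## Iterative correction

Matrix balancing removes multiplicative per-bin biases: each round divides
rows and columns by their sums normalized to the mean unmasked row sum and
accumulates the per-bin bias product, so the total count is preserved up to a
global rescaling and `corrected = raw / (b_i * b_j)` holds exactly.
Convergence is declared when the coefficient of variation of unmasked row
sums drops below `tol` (default 1e-5, default cap 200 iterations; the
convergence flag is honest). Zero-marginal bins are auto-masked first. On
rank-1 contaminated matrices (balanced target times outer product of biases)
the planted biases are recovered to better than 1e-6 relative error.

## Replicates

Replicate agreement is the Pearson correlation over unmasked off-diagonal
upper-triangle entries; merging is element-wise summation with the union of
masks. Merging proceeds below the 0.9 correlation gate, but warns and flags
the output — discarding data is the caller's decision. The pipeline order is
bin, correct, merge, then smooth; the source describes binning, correction
and smoothing in that order without fixing merge placement, and summation of
independently corrected replicates is scale-stable.

## Median smoothing (5C only)

Each nonzero unmasked element is replaced by the median of the existing
(in-bounds, nonzero) values in its 3x3 Moore neighborhood including itself,
all computed from the input matrix; zero elements pass through untouched so
absent interactions are never inflated. Zeros are also excluded from the
median multiset of a nonzero center: if they participated, a measured value
surrounded by five or more zeros would be smoothed to zero, silently growing
the zero set — excluding them makes the zero set exactly invariant, which is
the property the filter exists to protect. Even-cardinality medians are the
mean of the two central order statistics. The 8-connected window is a choice
("adjacent elements" admits a 4-connected reading) isolated behind one
function. C-TALE maps are corrected but not smoothed.

## TAD segmentation

The Armatus-style objective at a single resolution parameter γ: a candidate
domain over bins k..l (inclusive) scores

    q(k, l) = (Σ_{k ≤ i < j ≤ l} counts[i][j]) / (l − k + 1)^γ
    score(k, l) = q(k, l) − mu(l − k + 1)

where `mu(s)` is the mean of q over all contiguous windows of size s that
contain no masked bin (windows overlapping masked bins cannot become domains,
and their zeroed counts would deflate the mean). The globally optimal
segmentation into non-overlapping positive-score domains and background gaps
is found by the exact DP

    OPT(l) = max(OPT(l−1), max_{k} OPT(k−1) + max(score(k, l), 0)).

Ties prefer the gap (fewer domains), then the leftmost-longest domain, making
tracebacks deterministic across platforms. `min_size` defaults to 2 bins — a
1-bin domain has an empty intra-domain sum and is degenerate. Masked-bin runs
are forced gaps rather than compacted away, preserving genomic coordinates in
BED output. The DP is pinned by an exhaustive-enumeration oracle on all maps
with ≤ 12 bins; the default γ for study-scale data is 0.15, and
`gamma_sweep` reports the best γ over {0.05…1.0} against known boundaries.
Scoring is invariant under global rescaling of the matrix (q and mu scale
together).

## Compartment annotation

The classic eigenvector procedure: observed/expected normalization by the
per-distance mean over unmasked pairs, Pearson correlation matrix of O/E
columns over unmasked bins, first principal component by symmetric
eigendecomposition (deterministic up to sign; constant O/E columns are an
error naming the offending bins). The sign is then oriented against an
activity reference track — gene density, transcription or CpG density — with
A-like defined as positively activity-correlated. The display convention
defaults to `A_negative` (A-like bins carry negative PC1), matching how the
source data are presented; the convention flips the displayed sign only,
never the labels. Sign runs shorter than `min_run = 2` bins are absorbed into
the larger flank before borders are emitted: with ~90 bins and two expected
borders, single-bin compartments are noise. PC1 is scale-invariant and border
positions are stable under label involution.

## Interaction statistics

* **Virtual anchor** — mean ± SD of contacts between an anchor bin interval
  and every other bin (anchor-internal pairs excluded); a 1-bin anchor
  reproduces the matrix row exactly.
* **Region-pair samples** — unmasked bin-pair counts between two intervals,
  each unordered pair once, with an optional minimum genomic separation
  (e.g. >60 Kb = |i−j| > 12 at 5 Kb) for within-region comparisons.
* **Paired Wilcoxon signed-rank** — one-tailed, paired by identical (i, j)
  keys across two maps. Zero differences are dropped, ties take mid-ranks.
  For ≤ 25 effective pairs the exact tie-aware null distribution is computed
  by convolution over doubled mid-ranks (a DP over 2x-scaled ranks, so .5
  mid-ranks stay integral); above that, the normal approximation with tie
  correction. The exact route is validated against full 2^n enumeration and
  against scipy on tie-free data, and the test's type-I error is calibrated
  to 0.05 ± 0.02 under a Poisson null.
* **Contact scaling** — per-distance mean contact inside a region, optionally
  omitting pairs with both ends in an excluded sub-interval; the log-log
  slope against (d + 1) recovers a planted decay exponent within ±0.1.
* **Stratified contacts** — unmasked bins split into quantile groups of a
  per-bin track (quartiles by default; fixed thresholds were not specified at
  the source) and the count distribution returned per group pair.
* **Intergenic percentiles** — intergenic regions are the complement of
  merged gene spans; per-region fold change is log2((cov_b + ε)/(cov_a + ε))
  with ε = 1 read (unstated at the source; prevents log of zero), and
  percentiles are mid-rank percentiles within the full intergenic table so a
  query locus is ranked against the genome-span distribution.

## Motif scanning

A JASPAR PFM is converted to a log-odds PWM with the pseudocount (default
0.8, a common motif-tool default) distributed by the background composition:
`pwm[b,k] = log2(((counts[b,k] + pc·bg[b]) / (total_k + pc)) / bg[b])`. Both
strands are scanned (reverse strand = reverse complement, positions mapped
back to the forward strand); windows containing N are skipped; the hit
threshold is a fraction (default 0.8) of the maximum attainable score, the
standard relative-score convention since no absolute cutoff was published.
Peaks are labeled by the orientation of their best hits: both strands present
with the reverse motif upstream is "divergent" (motifs point apart), the
opposite order "convergent". Scanning agrees with biopython's PSSM scoring,
which serves as an independent cross-check, not the implementation.

## Synthetic data

The generator defines the conditions every recovery claim is tested under.
Expected counts follow

    λ(i, j) = base · (|i−j| + 1)^α · E^[same domain] · C^[same label] · M^[loop anchor]

with base scaled so the expected upper-triangle total equals `depth`, and
observed counts drawn Poisson(λ) — the standard noise model for sequencing
counts and the one ICE assumes. Defaults: decay exponent α = −1.0 (canonical
contact-probability scaling for mammalian-like chromatin; the source plots
scaling without stating an exponent); a 90-bin 30-Kb geometry over
chr14:9.8–12.5 Mb with compartment blocks A[0:11], B[11:73], A[73:90]
(a gene desert flanked by two gene-rich blocks, borders at the bins where the
study places them, 0-based) with domain boundaries at {11, 25, 40, 55, 73},
domain enrichment 2, compartment strength 2; and a 150-bin 5-Kb geometry over
chr14:11.70–12.45 Mb with eight contact domains and enrichment 3. Replicates
are independent Poisson resamplings of a map at a target depth; at 1e5 total
counts the default map passes the 0.9 replicate-correlation gate, and
correlation tends to 1 with depth.

Read-pair simulation emits labeled pairs over a restriction map, one
constructible witness per filter class (valid pairs ≥ 500 bp apart and > 5 bp
from sites on distinct in-range fragments; self-ligations on one fragment;
dangling ends < 500 bp apart across a site; duplicates as coordinate-exact
copies of a valid template; near-site ends within 5 bp; short-fragment ends
on a planted < 100-bp fragment). Filter tallies equal the simulation manifest
exactly, per class, for every seed — the closed loop that pins both modules.

What the generator does **not** emulate: capture/hybridization efficiency
gradients, mappability and GC bias (beyond what rank-1 bias tests cover
separately), translocations or copy-number structure, nested domain
hierarchies within one map (domains are a flat partition), distance-dependent
compartment mixing, or sequence-level read errors. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
generative model, not robustness to every artifact of real libraries.

## Problem sizes and numerics

Recovery experiments use 20 simulation seeds at depth 1e6 on the 90-bin
geometry; DP–oracle equivalence uses maps of 4–12 bins where exhaustive
enumeration is cheap; Wilcoxon calibration uses 1000 null replicates of 100
pairs; the smoothing contract is checked exhaustively on random 20x20 maps.
These sizes give stable estimates (binomial SE on a 95% recovery rate over
1800 bins is ~0.5%) while keeping the full suite fast. Floating-point
tie-breaking in the segmentation DP uses a 1e-12 slack so equal-score
alternatives resolve identically across BLAS builds; ICE convergence and
idempotence are asserted at the tolerance actually configured, not at machine
precision.
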