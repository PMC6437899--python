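# Methods

## Signal representation

The observation sequence is a matrix of non-negative integer read counts in
fixed-width bins (default 100 bp, 0-based half-open tiling; the terminal
bin of each chromosome may be truncated). Feature order is canonical:
accessibility, H3K27ac, H3K4me1, H3K4me3. When binning alignments, each
read contributes 1 to the bin containing its strand-aware shifted 5'
position; the default shift is 75 bp for ChIP-seq features (half the
expected 150 bp fragment, estimating the fragment center) and 0 for
accessibility assays, where the cut site itself is the signal. Shifted
positions beyond the chromosome end are clipped into the terminal bin, so
binning conserves reads. Bins with no reads are kept at zero; no
mappability masking is applied. Duplicate removal is assumed done upstream.
A pseudocount of 1 is added before any logarithm, so all log-counts are
finite; emission densities are always evaluated on pseudo-counted values.

Cross-sample normalization is plain quantile normalization per feature on
raw counts: the i-th smallest query value is replaced by the reference
quantile at plotting position i/(n−1) (linearly interpolated when lengths
differ); tied query values all receive the mean of the reference quantiles
their rank range spans, which keeps the mapping monotone. The core mapping
is real-valued; the count-matrix wrapper rounds back to non-negative
integers so downstream code sees one data type. Applied twice against the
same reference, the mapping is a fixed point, and it preserves ranks
exactly on tie-free input. Normalization operates genome-wide, not per
chromosome. A trained model stores 1001 evenly spaced reference quantiles
per feature — enough to reconstruct the reference distribution to well
below count resolution — rather than the full sorted vector.

## Emissions

Each state emits the four features independently with log-normal densities:
log x ~ N(μ, σ) per state and feature. The weighted fit is closed-form
(posterior-weighted mean and reliability-weighted unbiased standard
deviation of log-counts; with unit weights this is the ddof=1 sample sd),
which keeps the M-step trivial. σ is floored at 1e-3 so states capturing a
single coverage value keep a proper density; such degenerate states are
assigned a Kolmogorov-Smirnov fit distance of 0 by convention. Count-scale
state means are exp(μ + σ²/2).

## The constricted HMM

A model is (roles, initial distribution, transition matrix, boolean mask,
emissions); masked transitions are exactly zero and remain so through any
amount of re-estimation. Forward-backward runs with per-frame rescaling of
emission likelihoods plus scaled recursions, Viterbi fully in log space
(ties broken toward the lowest state index), both as numba kernels:
megabase sequences with 22 states decode in seconds. Baum-Welch
re-estimates transitions from expected counts restricted to the mask and
refits emissions with posterior weights; default tolerance 1e-4 in
log-likelihood, max 100 iterations, k-means seeding of the emission
parameters (seed configurable, default 0, states ordered by total emission
mean for determinism).

Viterbi training is the hard-EM variant used for the foreground modules:
per iteration, each training region is decoded with its first bin
restricted to N1 states and its last bin to N2 states (the constraint lives
in the lattice, not the model — training regions are anchored to start and
end at nucleosome positions, so both ends are constrained); transitions are
re-estimated from hard path counts with a smoothing count of 1e-6 added to
every allowed transition so none collapses to exactly zero from a finite
sample; emissions are never touched. Convergence is a path fixed-point,
default cap 50 iterations.

## Supervised construction

Foreground state selection ranks the five Baum-Welch states by the ratio of
count-scale emission means: top two by accessibility/H3K27ac become A;
among the remaining three, top two (enhancer) or bottom two (promoter) by
H3K4me1/H3K4me3 become N; the fifth is discarded. Ties at a selection
boundary warn and break toward the lowest state index. The N pair is
duplicated into N1 and N2 (N2 emissions are exact copies), the module mask
allows within-group transitions (including between the two states of a
group) plus N1→A and A→N2, rows are initialized from the 5-state fit
restricted to the mask and renormalized, and N2's intra-group rows are
copied from N1's. The module's start distribution is uniform over N1.

Composition places 10 background, 6 enhancer and 6 promoter states in one
matrix. Entry rates are computed exactly from the genome statistics
(399,124/70,292 elements, 3×10⁹ bp, 100 bp bins → 0.0133 and 0.0023 per
background bin; the printed 1.33%/0.23% are the two-decimal presentation)
and the existing background mass is rescaled uniformly by one minus the
total entry mass. The entry mass of a module is split over its two N1
states by the module chain's stationary occupancy; since the refined module
chain is absorbing in N2 that occupancy is degenerate and the split falls
back to 50/50 in practice. Each N2 state's exit mass equals its
corresponding N1 state's total mass into the A group (flanking nucleosomes
are expected to be equally sized) and is distributed over background states
by the background model's stationary distribution; N2 intra-group mass is
rescaled to keep rows stochastic. Emission parameters of the sub-models are
never altered, and the combined model is not re-trained. Initial
distribution: uniform over background. Models serialize to a versioned JSON
schema (parameters, mask, roles, features, reference quantiles); the round
trip is byte-identical.

## Training- and test-set construction

The region pipeline follows the published protocol: CAGE bidirectional
regions thresholded by tag count (≥11 for ESC-like depth, ≥5 for shallower
samples); k-means (k=5, fixed seed) on per-region mean log signal, keeping
the cluster maximizing mean z(accessibility) + z(H3K27ac) + z(H3K4me1) −
z(H3K4me3) — an explicit formalization of "strongest active-enhancer
signature", with the H3K4me3 sign separating promoter-like clusters;
anchoring to H3K27ac–ATAC–H3K27ac peak triplets with full span < 2 kb
(flanking defined by peak-center order, nearest flanker on each side,
narrowest qualifying span wins); and removal of *both* members of any pair
of regions with edge-to-edge gap < 2 kb, keeping only isolated elements,
consistent with the model's assumption of background on both flanks.
Promoter training sets run annotated TSS regions through the same pipeline.
Background sets sample 2 kb windows at rough mammalian genome proportions
(10% enhancer, 5% active promoter, 5% inactive promoter, 10% genic, 70%
intergenic), reject windows overlapping annotated enhancers or active
promoters, and refill those quota slots with genic/intergenic draws in
proportion. Test sets merge raw regions within 500 bp, drop merged regions
within 2 kb of a TSS (TSS as 1-bp midpoints), and re-center survivors on
the summit of the highest-scoring overlapping ATAC peak, preserving the
merged width; survivors without a peak are dropped. Cross-validation
partitions enhancers into k near-equal folds and pads each test fold with
background negatives to a configurable positive fraction (default 10%,
mirroring genomic proportions). All sampling takes explicit seeds.

## Prediction and evaluation

Chromosomes are decoded independently (paths never cross chromosome
boundaries). Maximal runs of enhancer (promoter) roles become elements with
their N1/A/N2 substructure; the element score is the maximum per-bin
accessibility posterior inside the element (posteriors peak at element
centers, so the maximum is the natural summary). Per-module scores are
emitted; the enhancer-module score is the headline certainty. Predictions
are written as BED (score = round(1000·posterior)), per-bin scores as
bedGraph.

The precision-recall curve and its area use the step-wise
average-precision estimator (sklearn's), stated explicitly because
estimator choice shifts the area by up to ~0.01. The Viterbi operating
point counts a test positive as recalled if overlapped by ≥1 bp by a
predicted element of the right kind, and computes precision only over
predictions that overlap any test region — predictions elsewhere on the
genome are simply outside the test set's universe. With no qualifying
predictions, precision is reported as 0 with a warning. Distances to
features are center-to-center to the nearest feature; TSS overlap asks
whether the element interval contains the TSS coordinate.

## Synthetic ground truth

The generator samples a state path and counts from a fully specified
22-state model built by the same composition code as training, so entry
rates match the genome-scale defaults exactly. Background states carry low
log-means (0.3–1.2) varied across states and features; foreground modules
put the informative contrast on top of a 0.75 baseline — enhancer N states
high H3K27ac/H3K4me1, promoter N states high H3K4me3, A states high
accessibility — with the two states of each group offset by 0.1. The
"easy" setting uses ~2 log-units of contrast at σ = 0.5; "hard" shrinks
contrast to ≤ 0.5 log-units at σ = 0.8. Group dwell is geometric with mean
~3 bins (leave probability 1/3), giving elements of ~900 bp on average.
Counts are rounded log-normal draws clamped at zero — exactly the fitted
emission family, so recovery tests are well specified; Poisson sampling
noise, mappability artefacts, copy-number effects and peak-caller noise of
real data are deliberately absent. Passing the synthetic benchmark
therefore demonstrates correctness of the training and decoding machinery
under the model's own assumptions, not performance on real chromatin.

Two reported diagnostics need a caveat. First, log(count+1) ≈ μ only where
exp(−μ) is negligible; recovery of emission means is asserted for
high-signal states (μ ≥ 3). Second, the median KS distance between binned
counts and fitted log-normals on synthetic data (~0.16) is dominated by the
discreteness of small counts — the empirical CDF of an integer-valued
sample steps against a continuous fit — and is a property of the rounding,
not a fitting failure; on continuous well-specified samples the same
fitting code reaches median KS < 0.05.

The default synthetic genome is 2 chromosomes × 5×10⁵ bins at 100 bp
(10⁶ bins total), seed 0. The end-to-end benchmark trains on regions from
chromosome 1 (up to 300 isolated truth elements per class, 2 kb isolation
as in the real protocol, elements ≥ 500 bp so each region spans ≥ 5 bins;
300 element-free 2 kb background windows) and evaluates on held-out
chromosome 2 against a 1:9 positive:negative test set. These sizes keep
the whole pipeline at roughly a minute on one CPU while leaving ~5,800
true enhancers on the evaluation chromosome.

## Design choices and limitations

- The sub-model surfaces are tool-shaped functions around three core
  classes (`SignalMatrix`, `EmissionModel`, `ConstrictedHMM`); the CLI
  covers the steps users run from a shell (bin, normalize, simulate,
  train, predict, evaluate), while region-set construction is a library
  API, since its many external inputs (CAGE, peaks, annotation) vary too
  much for a fixed flag set to help.
- Exactly two foreground modules (enhancer, promoter); arbitrary module
  sets are out of scope.
- Posterior decoding is never used for segmentation — it can violate the
  grammar; it only provides certainty scores.
- Whole-genome fits assume the four canonical features; other feature sets
  work through the same machinery but the state-selection ratios are
  defined only for the canonical four.
- Negative-binomial/negative-multinomial emission alternatives are not
  implemented.
- BED intervals are 0-based half-open throughout; "within 2 kb" filters
  use edge distances, "pairwise distance" in neighbor removal is the
  edge-to-edge gap.
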