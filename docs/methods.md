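# Methods

This note documents the models, defaults and numerical choices behind
`maldianova`, and what the synthetic benchmarks do and do not show.

## Pre-processing chain

Raw profile spectra (one intensity trace per acquisition on a shared
m/z axis) pass through, in order:

1. **Log transform** `x → log(x + c0)`, guard `c0 = 1` so zero
   intensities stay finite.  Negative raw intensities are an error.
2. **Median smoothing**, centered window of 9 points; the window
   shrinks at the edges rather than padding.
3. **Tophat baseline removal**: subtraction of the morphological
   opening with a flat structuring element, default width 151 indices —
   much wider than peaks (Gaussian σ ≈ 3 indices) and narrower than
   baseline undulation, so peaks survive and the baseline does not.
   Output is guaranteed non-negative and ≤ input.
4. **CWT peak picking**: Mexican-hat continuous wavelet transform over
   integer scales 3…16 (PyWavelets), ridge lines tracked coarse-to-fine
   by linking per-scale local maxima within one scale-width (gap
   tolerance 2 rows).  Ridges shorter than 7 rows are dropped, as are
   ridges whose maximal coefficient is below 3× the noise level, the
   0.95 quantile of |finest-scale coefficients|.  The apex is the
   finest-scale ridge position refined to the intensity centroid in a
   ±8-index window, iterated to convergence.  The refinement exists
   because the raw ridge endpoint can stall several indices off-center
   on median-flattened peak tops; the centroid is deterministic and
   translation-equivariant, which alignment depends on.
5. **Alignment**: reference peaks are picked from the point-wise mean
   of all baselined spectra.  For each spectrum, each reference apex is
   matched to the nearest observed apex within ±30 indices; the
   spectrum's single integer shift is the mean of the signed matched
   distances, rounded half away from zero.  Zero matches give shift 0
   with a warning flag.  The continuous trace is then translated
   (edge-value fill).  One pass only; no multi-pass refinement.
6. **Quantification**: per reference apex, the maximum intensity in a
   ±4-index window.  A window maximum was chosen over area integration
   for robustness to residual ±1–2-index misalignment.
7. **Variance stabilization** `v → log(v + 0.1) + offset` (offset
   defaults to 0; it is cosmetic).  Under a multiplicative error model
   the spread of replicate intensities grows linearly with the mean;
   after the double log the spread is flat, which the variance
   diagnostic (standard error vs. mean per replicate group, with linear
   and lowess fits, default lowess fraction 2/3) verifies.
8. **Replicate averaging**: technical replicates are not independent,
   so one profile per biological sample is formed as the arithmetic
   mean of its replicate profiles on the stabilized scale.

A note on alignment frames: the mean spectrum of drifted data carries a
small constant index offset relative to any individual spectrum.  All
spectra are aligned consistently to that frame, so downstream
quantification is unaffected, but "absolute" shift values are only
identifiable against a drift-free reference; the recovery benchmark
therefore builds its reference from a paired drift-free simulation.

## ANOVA

All tests are nested linear-model F-tests on treatment-coded design
matrices fitted by least squares:
`f = ((RSS1 − RSS2)/(p2 − p1)) / (RSS2/(n − p2)) ~ F(p2−p1, n−p2)`.
Main factors (diet, genotype, week) are each tested against the full
main-effects model with that factor removed — an order-independent,
type-II-style comparison; sequential sums of squares were rejected
because results would depend on term order.  The genotype × diet
interaction is tested by adding it to the main-effects model.  Empty
design cells make some interaction columns all-zero; they are dropped,
flagged, and p1/p2 are taken as matrix ranks.  Week enters as a
categorical factor (4 levels) by default; a numeric coding is available.
Degenerate cases: constant responses give p = 1 with a flag; a
saturated full model with remaining reduced-model residual reports the
p → 0 limit with a flag.  The mixed-effects alternative (random
technical-replicate effects) is deliberately not implemented; replicate
averaging is the supported path.  Bonferroni correction is the only
multiplicity control, with a helper that reports thresholds rounded to
one significant digit.

## Redundancy clustering

Peak intensity profiles (one value per sample) are clustered by UPGMA
average linkage under d = 1 − ρ (Pearson).  UPGMA was preferred over
WPGMA as the common default meaning of "average linkage".  Constant
profiles have undefined ρ and are dropped with a warning.  Node
annotations: mean pairwise member correlation (leaves: 1 by convention)
and four p-values from the factorial ANOVA of the point-wise mean of
the members' z-transformed profiles (sample sd, n−1).  Leaves use their
own raw profile — the F statistic is invariant under the affine
z-transform, so leaf p-values equal the per-peak table bit for bit.
Export is Newick (internal nodes named `n<i>`) plus a JSON side-table
with −log10 p per factor on four independent colour scales.

## Synthetic data

The generator emulates the study the package is built around: 3
genotypes × 3 diets × 4 weeks with per-cell spectrum/sample counts
matching the published design (1122 spectra, 155 samples, up to two
preparations × four replicate acquisitions per sample; two cells
empty).  Peaks come in families sharing a parent protein: per sample,
family f's peaks draw log-amplitudes
`base + effects + σ_bio(√ρ·u_family + √(1−ρ)·v_peak)` so ρ sets the
within-family correlation; technical replicates share the biological
draw and add a per-peak log-normal factor `exp(σ_tech·ε)`.  Defaults,
chosen once as plausible for MALDI-TOF profiling and not calibrated to
any instrument: σ_tech = 0.5 (raw-scale CV ≈ 50 %), σ_bio = 0.4,
base log-heights U[5, 9] (raw heights ≈ 150–8000 counts), Gaussian
peak shape σ = 3 indices, baseline = decaying exponential (amplitude
60, 5 e-folds) plus a slow half-sine (amplitude 20, 2.5 periods,
random phase), 3 % point-wise multiplicative jitter, integer index
drift uniform in ±10 (±15 in alignment benchmarks).  The axis is
linear in m/z 700–10,000; 32,000 points mirrors the raw data, 1,500–
4,000 points are used in tests for speed.  Planted factor effects are
log-intensity shifts keyed to factor levels, including
genotype × diet combinations.

Not emulated: isotope envelopes, charge states, m/z-dependent peak
width, calibration physics, anti-correlated peptide relationships.
Passing benchmarks therefore show the statistical machinery recovers
planted structure under this error model, not that any instrument
artefact is handled.

## Feature selection and classification

Three strategies feed the same CART-style decision tree (Gini,
max depth 5, min leaf 5 — conservative caps for ~60–155 samples):
the plain ANOVA filter; cluster representatives (cut the dendrogram at
distance 0.3, rank flat clusters by node p-value, take each top
cluster's min-p member — representatives are pairwise from distinct
clusters by construction); and an ant-colony wrapper.  ACO defaults
follow the reference configuration of 200 ants × 100 iterations;
internals unstated there are package choices: evaporation 0.1,
pheromone bounds [0.01, 10], α = β = 1 with heuristic −log10 p,
iteration-best reinforcement by 1 − error, fitness = stratified 3-fold
internal CV error, subset fitness memoized.  Reported performance is a
pooled confusion matrix from stratified 10-fold CV (folds reduced with
a warning if a class is smaller than the fold count).  The permutation
p-value scores `n_random` (default 1000) uniformly drawn same-size
feature sets with the *same* folds as the observed set and applies an
add-one pseudo-count, so its floor is 1/(n_random+1).  Whether random
sets should share folds was an open choice; same-fold scoring removes
fold noise from the comparison.

## Problem sizes in the shipped benchmarks

Tests and the acceptance script run at desk scale, chosen as the
smallest sizes at which each property is stable: axes of 1,500–3,000
points, 200 spectra for drift recovery, 2,000 null peaks for type-I
calibration, 10,000 replicate draws for the variance slopes, 60-sample
profile matrices with 5 planted families + 20 noise peaks for
clustering and selection, ACO at 30 ants × 10–15 iterations.  The
original study's scale (261 peaks from 32,000-point spectra) is not
reproduced because its raw data are not public; the design bookkeeping
(1122 → 155) is exercised in full.

## Known limitations

- Alignment estimates one global integer shift per spectrum; warping or
  m/z-dependent drift is out of scope.
- No TIC or quantile normalization: the only intensity transforms are
  the two logs.
- Week is modelled as categorical; trend tests over age are not
  provided.
- The ACO wrapper is deterministic only for a fixed seed and its
  performance depends on the internal-CV signal; with very small
  samples the internal folds can be noisy.
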