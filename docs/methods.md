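# Methods

This note records the models, conventions and numerical choices behind the
package, in the order data flows through it.

## Data model

A field of view is an H × W × 47 cube of non-negative intensities plus an
ordered channel table.  The 47 channels are combinations of 18 LED
excitations (358–476 nm, ±5 nm) and 5 emission filters (414 ± 23, 451 ± 53,
575 ± 29.5, 675 ± 33.5 nm bandpass and a 594 nm longpass).  Which 47 of the
90 possible pairs an instrument acquires is configuration; the default
table picks, per excitation, filters whose band lower edge clears the
excitation center by a 10 nm guard band, round-robin over each
excitation's eligible filters until 47 pairs are collected.  This keeps all
18 excitations and all 5 filters in play and every pair Stokes-valid.  The
table is ordered filter-major (one excitation scan per filter block), so a
spectrum over channel index is piecewise smooth — which the reference
smoothing below exploits.  Cubes carry a `stage` tag
(raw → preprocessed → calibrated) and a step history; the preprocessing
functions enforce the order cosmic-rays → denoise → background → flatten →
calibrate.

## Preprocessing

**Cosmic rays.** A pixel is a spike if it exceeds the median of its 3×3
spatial neighbourhood (same channel, edge-replicated, center included) by
more than `z · 1.4826 · MAD` of that neighbourhood, with z = 8; spikes are
replaced by the neighbourhood median.  On i.i.d. Gaussian noise this rule
intrinsically flags ≈ 0.085% of clean pixels, so z = 8 is about as low as
one can go while altering < 0.1% of clean data.  Single-pixel image
structure (speckle at the window scale, 1-px protrusions) is by definition
indistinguishable from a spike under any such rule.

**Denoising.** In place of a dedicated hyperspectral restorer, a generic
two-stage denoiser: (1) the pixels × channels matrix is truncated to its
top `denoise_rank` (default 8) singular components — per-pixel spectra in a
field are mixtures of a few endmember fluorophores plus background, so the
scene is low-rank in the spectral dimension; (2) each channel image is
soft-thresholded in a CDF 9/7 biorthogonal wavelet basis (`bior4.4`,
2 levels) at the universal threshold `σ√(2 ln n)` with σ from the finest
diagonal subband's MAD.  Soft thresholding slightly shrinks genuine edge
coefficients, which costs ~1% of the masked-mean signal at sharp cell
boundaries; this is the dominant term in the end-to-end error budget.
Negative outputs are clipped to zero and counted.

**Background and flat field.** The per-channel background level is the
median over mask-background pixels (median rather than mean: robust to
unmasked debris).  The illumination surface is fitted *before* subtraction
(zero-clipping would destroy it afterwards): the pre-subtraction channel
image is smoothed by normalised convolution over background pixels only (so
bright cells do not bleed into the estimate), a degree-2 2-D polynomial is
fitted to the smoothed background, normalised to mean 1, and divided out.
Degree 0 reduces to no-op after the mean-1 normalisation.  Because the
background level is subtracted as a scalar while the true background rides
the illumination ramp, a residual of order `background · ramp amplitude`
(~1% of signal at the defaults) survives; it is part of the ≈1.5% pooled
recovery error.

**Calibration.** Water-blank and calibration-fluid spectra give per-channel
gains `g_k = reference_k / (measured_k − water_k)`; channel k is multiplied
by g_k and the gains are recorded in the sidecar.  Reference spectra are
wavelet-smoothed one emission-filter block at a time — smoothing across the
whole 47-vector would smear the jumps between filter blocks; blocks shorter
than 8 channels are left untouched.  A non-positive denominator in any
channel aborts calibration naming the channels.

## Features

Per cell (a labelled mask region on a calibrated cube): 7 intensity
statistics per channel (mean, median, sample SD, sample skewness, excess
kurtosis, 10th/90th percentiles; skewness/kurtosis are 0 by convention for
zero-SD populations), 5 co-occurrence statistics per channel (contrast,
correlation, energy, homogeneity `Σ p/(1+(i−j)²)`, Shannon entropy in
bits), 9 morphology features, and mean-intensity ratios for a configured
channel subset.  The co-occurrence matrix uses 16 grey levels quantised
over the cell's own min–max (making texture invariant to affine intensity
maps), offsets (0,1), (1,0), (1,1), (1,−1) with per-offset symmetric
normalised matrices averaged, and masked pixels only (hand-written: the
stock GLCM implementations support neither masks nor this convention).
Degenerate single-level cells get contrast 0, correlation 0, energy 1,
homogeneity 1, entropy 0.

DNA-content gating locates the G1 mode m as the peak of a Gaussian KDE of
total DAPI intensity and cuts at 1.25 m (G1/S) and 1.75 m (S/G2) — default
conventions, configurable; M phase only via explicit override.  Stain
positivity scores `(total − background · area)/area` are thresholded by an
exact sample-based Otsu (between-class variance maximised over all sorted
splits; the histogram variant can misplace the threshold on small
continuous score sets) or an absolute cutoff.

Table assembly joins features to labels on (field_id, cell_id), drops
non-finite rows (logged), and removes one member of every feature pair with
|Pearson r| > 0.95, keeping the higher-variance member (ties: the
lexicographically smaller name survives), scanning in catalog order for
determinism.

## Classification stack

Per cross-validation fold, fitted on the training fold only: z-scoring
(zero-SD features dropped), MRMR selection, PCA retaining 99% variance,
and an LDA projection to `n_classes − 1` dimensions obtained from the
generalised eigenproblem `S_b w = λ (S_w + 10⁻⁶·tr(S_w)/p·I) w` (pooled
within-class scatter; the trace-scaled ridge keeps the problem
well-conditioned), with a deterministic sign convention.

MRMR is the MIQ greedy variant: relevance V(f) = mutual information between
the feature (10 equal-frequency bins) and the class; redundancy W(f|S) =
mean MI with already-selected features; first pick argmax V, then argmax
V/(W + 10⁻¹²), ties broken by feature name.  The default selection size is
min(50, features available) for status tasks and 100 for the doublings
task.

Class imbalance is handled inside the training fold, in LD space: ADASYN
(k_density = 5; synthetic minority points on segments toward minority
neighbours, allocated by local majority density, falling back to uniform
allocation when no minority point has majority neighbours) or uniform
down-sampling of the majority.  Classifiers: linear SVM (C = 1), polynomial
SVM (degree 3, scaled kernel) or LDA.  Folds are stratified 5-fold
(seeded; fold count is a package default, not a claim about any particular
study); AUC comes from the continuous decision values, and
sensitivity/specificity are read at each fold's Youden-optimal point — an
explicit convention, since many operating points are defensible.

Line heterogeneity: per channel-mean feature, a Kruskal–Wallis test across
lines with Benjamini–Hochberg control at 0.05; the reported quantity is the
fraction of channels significant.

## Growth potential

Doubling labels are `round(arrest_total − cumulative_at_imaging)` from
per-line passage logs; cells of one line+passage share a label.  Per
evaluation repeat, half of every doubling class (floor(n/2), uniform,
seeded) is withheld; the embedding (z-score → MRMR top 100 → PCA → LDA over
the doubling classes, all `n_classes − 1` dimensions kept) is refitted on
the retained cells only, so withheld cells never touch scaling, selection,
PCA, LDA or the KNN reference set.  Withheld cells are projected and
classified by the coarse KNN: among the k = 400 nearest training points
(Euclidean, full LD space), each label present gets the mean distance of
its members, and the smallest mean wins; ties go to the larger member
count, then the smaller label.  With k = 1 this reduces to classic
nearest-neighbour.  The per-class aggregate is the median of the withheld
cells' predictions (half-integer for even counts); over 30 repeats the
report carries the mean aggregate, an empirical 2.5/97.5-percentile
prediction interval (assumption-free, matching the spirit of a 95%
prediction band), and RMSPE/MAE of the mean aggregates across classes.
RMSPE ≥ MAE always; predictions flatten at the label range's ends because
the classifier cannot extrapolate beyond observed classes.  The k-sweep
shares repeat seeds across k (identical splits and embeddings), so the
curve isolates the neighbourhood size.  Age clustering is k-means (10
seeded restarts) on the first two LD components, clusters reported in
descending mean-label order.

## Synthetic data

The generator emulates the statistical structure the analysis assumes —
not the optics.  Three endmember spectra (NAD(P)H-like: excitation ~351 nm,
emission ~450 nm; FAD-like: ~450/535 nm; lipofuscin-like: broad red) are
smooth Gaussian response surfaces over the channel table's
excitation/emission coordinates; they give the pipeline realistic spectral
correlation, with no claim of photophysical accuracy.

*Status populations* (default n = 300, 3 lines) draw per-cell channel
signatures `base_k · (1 + line_k + state shifts_k + ε_k)` with
ε ~ N(0, 0.15) per channel and per-line offsets of SD 0.05.  Senescent
cells (1/3 of the population) get a +1 within-class-SD shift in 10 red
channels plus 1.6× hypertrophic radius; STRO-1, ALP and cell-cycle states
get analogous smaller shifts in their own channel blocks.  DAPI totals are
drawn at m, 1.5m, 2m (5% CV) for G1/S/G2.

*Aging populations* use 24 doubling classes {0..19, 21, 23, 25, 28}
(range 28→0 with gaps at the high end, as lines differ in how far they
get), 100 cells per class, spread over lines whose passage logs arrest at
distinct totals in [28.05, 29.8] with decelerating increments and
reproduce the class labels exactly under the rounding rule.  The spectral
drift direction (lipofuscin up, FAD up, NAD(P)H down) accumulates 60%
relative change in the most affected channels over the 28-doubling
lifespan.  Heterogeneity has two parts, chosen once: per-channel
cell-to-cell noise equal to the drift accumulated over 8 doublings, and a
shared "metabolic age" jitter of 4 doublings RMS along the drift — the
shared term makes within-passage populations genuinely overlap (which is
why median aggregates are needed at all) while leaving the first LD
component rank-correlated > 0.8 with the labels.  Old cells hypertrophy up
to 1.6×; class-0 cells are flagged senescence-positive with probability
0.9.  The null variant sets drift and hypertrophy to zero and must drive
recovery to chance.

*Rendering* draws cells as rotated, area-preserving ellipses (a cross-shaped
morphological opening removes degenerate single-pixel rasterisation tips,
which would otherwise be indistinguishable from cosmic rays), with
multiplicative log-normal speckle (mean-normalised per cell, so noise-free
masked means equal the true signatures exactly).  The instrument model is
`(signal/gain + background) × ramp` followed by Poisson photon noise
(10⁴ photons per intensity unit), Gaussian read noise (SD 0.01) and
single-pixel cosmic-ray spikes; the illumination ramp multiplies the
background as well as the signal, since both are fluorescence seen through
the same optics.  Reference spectra are generated so that the calibration
formula inverts the known gains exactly in the noise-free case.  Point
spread, chromatic aberration and photobleaching are out of scope.

Everything is driven by one seed per scenario; equal seeds give bit-equal
outputs, and a scenario hash is recorded in every product.

## What the tests do and do not show

The synthetic populations have Gaussian, channel-independent heterogeneity,
binary-edged cells, and exactly consistent labels.  Passing recovery tests
therefore demonstrates that the *pipeline* is correct and leak-free under
its own assumptions — not that real MSC data will reach the same AUCs or
doubling errors, which depend on biology and instrument specifics the
generator does not model.  Oracle tests (coarse KNN vs brute force, MRMR vs
exhaustive criterion evaluation, AUC vs the Mann–Whitney statistic, LDA vs
its two-class closed form Σ⁻¹(μ₁−μ₂)) are exact and independent of those
assumptions.

## Problem sizes and defaults

Test and acceptance runs use the generator defaults: 300 cells for status
tasks, 24 × 100 cells for the aging task (30 repeats), a 160×160 px field
with 6 cells and 50 injected spikes for preprocessing recovery, and small
(18–48 cell) rendered datasets for the CLI chain.  These sizes were chosen
so the full suite completes in a few minutes on one CPU while leaving every
statistical margin wide; all are configurable through `Scenario` and the
CLI config file.

## Known limitations

* The flat-field correction assumes the illumination surface is a low-order
  polynomial and that background pixels exist in every field; a measured
  blank-dish image can be substituted via configuration but is not modelled
  by the generator.
* The universal-threshold wavelet shrinkage biases sharp-edge signal
  slightly (~1%); rank truncation assumes spectrally low-rank scenes.
* Sensitivity/specificity depend on the Youden-point convention; other
  operating points will differ.
* The coarse KNN cannot extrapolate beyond the observed label range, so the
  extreme doubling classes are biased toward the interior (visible as the
  plateau in the prediction-vs-truth curve).
* With tens of cells, the 0.95 correlation filter removes many texture
  features simply because small-sample correlations are noisy; at the
  default population sizes this is not a concern.
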