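# Methods

`specseed` implements a complete near-infrared hyperspectral workflow for
screening defective (insect-damaged) seeds: reflectance calibration and ROI
spectrum extraction, spectral pretreatments, wavelength selection by three
routes (SPA, CARS, and a CNN with a trainable feature-weight gate scored by
label-permutation importance), and classification by an attention CNN and
three reference models. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic data can and cannot
show.

## Reflectance calibration and ROI extraction

Raw line-scan counts are converted to relative reflectance with white
(~100 % target) and dark (shutter closed) reference cubes,

    Re = (Ir − Id) / (Iw − Id),

applied per pixel and band. The calibration is affine-invariant under a
common positive gain and monotone in the raw counts; positions where
Iw ≤ Id are a hard error (they indicate a broken reference), reported with
the affected pixel count.

Seeds are segmented on the band-mean reflectance image by Otsu's threshold
(a fixed threshold is accepted too), cleaned by a 3×3 morphological opening
then closing, filtered by a minimum area (default 20 px), and labeled as
8-connected components in raster order. Each seed's spectrum is the
arithmetic per-band mean over its pixels. The instrument's default grid is
866.4–1701 nm in 254 evenly spaced bands; analyses drop the first 9 noisy
bands, leaving 245. The crop is defined by band count, not by a nm
interval: on an even 254-point grid a ≥897.4 nm cut would keep only 244
bands, so "drop the first 9" is the count-preserving reading; nm-interval
cropping is also provided.

## Pretreatments

* **Savitzky–Golay** (window 11, polynomial order 1): local least-squares
  smoothing. Edge points are refit on the truncated one-sided window, which
  keeps the filter exact on straight lines everywhere (scipy's default edge
  interpolation does not have this property for the outermost points under
  truncation; we verify exactness against a brute-force sliding-OLS oracle).
* **Detrending (DE)**: subtract each spectrum's own OLS line over
  wavelength; residuals have zero mean and zero fitted slope, removing
  additive baseline drift.
* **MSC**: regress each spectrum on a reference (the mean spectrum of the
  fitting partition, stored so test data reuses the training reference) and
  correct to (x − a)/b. Rows with |b| < 1e-8 are left untouched with a
  warning.
* **z-score**: per-band standardization with training-partition statistics
  (population sd, ddof = 0); zero-variance bands map to zeros.

The classification pipeline runs SG first, then one branch (DE or MSC), and
z-scores at modeling time. Classical selection runs on preprocessed but
unstandardized spectra; the CNN selector takes standardized input.

## Classical wavelength selection

**SPA** chains start at every column; each step adds the unselected column
with the largest norm after projection onto the orthogonal complement of
the selected span (computed by iterative deflation, verified index-for-index
against an explicit pseudoinverse-projection oracle). For every size
k = 1..50 the best chain is scored by 5-fold CV-RMSE of a multiple linear
regression on 0/1-coded labels; the subset minimizing RMSE wins, ties going
to the smaller k.

**CARS** runs 50 Monte-Carlo iterations. Each fits a PLS regression
(components capped at 10, mean-centered, unscaled) on a random 80 % row
sample restricted to the currently retained bands, weights bands by
normalized |PLS coefficient|, enforces the exponential retention schedule
r_i = a·e^(−b·i) with r_1 keeping all L bands and r_50 keeping 2
(b = ln(L/2)/(n_mc−1), a = e^b), draws the new retained set by weighted
sampling without replacement, and records the set's RMSECV (stratified
K-fold; component count chosen on the same folds by minimum RMSE). The
subset at the RMSECV minimum is returned with the full criterion curve.

## CNN feature selection (feature-weight gate + permutation importance)

A trainable score vector w (length L) is softmax-normalized into strictly
positive coefficients c summing to one; the gated spectrum c ⊙ x feeds a
1-D CNN: Conv(127 kernels, width 64) → MaxPool(2, stride 1) → Conv(245, 32)
→ MaxPool → Flatten → Dense(10) → Dropout(0.25) → softmax(2). Kernel counts
are literal at L = 245 and scale proportionally for other band counts;
widths clip when spectra are shorter than a kernel. The loss is
cross-entropy plus λ·Σ c_k² (λ = 0.15), whose minimum over the simplex is
the uniform gate — mass concentrates only where classification pays for it.
Training: Adam (β1 = 0.9, lr 1e-3 with inverse-time decay 1/(1+1e-4·t)),
100 epochs, batch 4, weight decay 0.1 on conv/dense kernels.

Importance is a label-permutation scheme: S1_k is the trained coefficient
for band k under true labels; the labels are shuffled five times and the
network retrained from scratch each time; S2_k is the 75 % quantile of the
null coefficients; the score is IS_k = ln(1e-10 + S1_k/S2_k), with IS < 0
marking a band as uninformative. Selection keeps the top 10 % of bands by
IS (floor(0.10·L); 24 of 245) and then drops negatives; ties at the cut go
to the lower band index.

**Null amplitude matching (default).** Gate movement scales with how long
the cross-entropy stays informative. On easily separable data the
true-label run converges within epochs and its gate barely leaves uniform,
while label-shuffled runs memorize slowly and accumulate large, structured
gate movement (bands near the spectrum edges sit in fewer convolution
windows and systematically receive less gradient). Comparing a weakly
moved S1 against strongly moved nulls then ranks by the structural artifact
rather than the signal. The default therefore rescales each null run's
deviation from the uniform gate to the true run's deviation norm before
taking the per-band quantile: the null's per-band *shape* — what the
permutation null is meant to calibrate away — is preserved at a comparable
amplitude, the structure cancels in the ratio, and the sign rule keeps its
meaning. The raw per-band quantile (`perband`) and a quantile pooled across
bands and runs (`pooled`) remain available; on hard tasks where the true
run trains as long as the nulls all three behave similarly.

Two further conventions: the natural logarithm (the base only rescales IS
and cannot flip the sign rule), and fresh initializations for the null
runs. A non-trainable gating variant softmax(x ⊙ x) ⊙ x — reading the gate
pre-activation as the input's elementwise self-product — is provided for
comparison but not used in training, since a fixed gate leaves nothing for
the loss to regularize.

## Attention CNN classifier

A squeeze-excitation gate treats the L wavelengths as channels of unit
spatial extent (squeeze = identity): s = sigmoid(W2·relu(W1·x)) with
bottleneck width max(1, floor(L/8)) and no biases; the reweighted spectrum
s ⊙ x (gates strictly in (0,1), so components shrink but never flip sign)
is re-laid as a length-L single-channel sequence for three conv blocks
(16/64/128 kernels of width 3, ELU, MaxPool 2 stride 1), then Flatten and
softmax(2). Training: Adam as above, 200 epochs, batch 32, weight decay
0.008 on conv kernels only, no dropout. Depth reduces automatically below
L = 9; subsets from any selector (L = 23, 24, 29, 34, …) run unchanged. An
ablation flag replaces the gate by the identity for comparison runs.

## Numerical choices

* **All network arithmetic is float32** with im2col GEMM convolutions;
  training is exactly reproducible for a fixed seed (single-threaded,
  deterministic kernels, named RNG substreams for initialization, batch
  order, dropout, and label shuffles).
* **Weight decay is decoupled** (AdamW convention: p ← p − lr·wd·p for
  kernels). Folding the penalty into the gradient lets Adam's
  per-coordinate normalization amplify it to the full learning rate
  whenever data gradients are small — at wd = 0.1 that collapses the
  selection network into a dead constant predictor before it can learn.
* **MaxPool ties** (window 2, stride 1) route gradient to the left element;
  pooling is the identity on length-1 inputs so clipped architectures stay
  well-defined.
* **Probability clipping** at 1e-12 before logs; softmax computed with the
  max-subtraction trick.
* **Metric rounding**: AC/SE/SP are percentages rounded half-up to two
  decimals; undefined metrics (empty class) are reported missing, and a
  split that leaves a partition single-class is redrawn with a warning.

## Synthetic data: what it emulates and what it does not

The generator produces two-class reflectance spectra with the structure of
mean seed spectra: a smooth declining base near reflectance 0.45 (sigmoid
0.55 → 0.40) with Gaussian absorption troughs at 959.3, 996.9, 1159.1,
1239.1 and 1331.5 nm (widths 16–32 nm, depths 0.010–0.022); a class-mean
offset of 0.02 reflectance confined to 12 contiguous informative bands
around 1265–1302 nm, with the defective class lower; and per-sample
multiplicative scatter (sd 0.02), linear baseline tilt (sd 1e-5 per nm),
and white noise (sd 0.004). Defaults are 200 samples per class on the
254-band grid with a 7:3 random split (280/120). One named RNG substream
per artifact (gains, tilts, noise) keeps draws stable when n changes.

Synthetic reference scenes plant morphologically regular elliptical seeds
(invariant under the 3×3 opening/closing used in segmentation) on a dark
background, with smooth per-band white-reference counts and constant dark
counts, so the calibration equation recovers the planted reflectance
exactly and the true mask is available as an oracle.

This emulation supports exact-recovery and regime tests; it does not model
kernel chemistry, spatial reflectance texture within a seed, detector
nonlinearity, or wavelength-correlated noise, and it makes no attempt to
reproduce any real instrument's absolute spectral means. Passing tests
demonstrate that the algorithms are implemented correctly and behave as
designed under known ground truth — not that any particular accuracy will
transfer to real seed data.

## Reference experiment scales

Two protocols in `specseed.experiments` are shared by the test suite and
`scripts/acceptance.py`, with problem sizes chosen so each full study runs
in minutes on a single CPU:

* **Planted-band recovery** (CNN selector): 128-band grid, 100 samples per
  class, 30 training epochs per run (1 true + 5 null runs per seed); kernel
  counts scale with the band count as described above; all other
  hyperparameters at protocol defaults. The pipeline is detrend → z-score
  — deliberately without SG smoothing, which would spread the planted
  12-band effect onto ~5 neighbors per side and make band-level recovery
  against the planted truth ill-posed.
* **Attention-classifier accuracy**: full data scale (400 samples, 245
  analysis bands, 7:3 split, SG + DE + z-score) with 60 training epochs —
  training and test accuracy saturate within the first ~20 epochs on
  synthetic data, so the shorter schedule measures the same plateau.

## Known limitations

* Binary classification only; the selection network assumes two classes.
* The CNN engine is CPU-only and sized for spectra-length inputs; it is not
  a general deep-learning framework.
* The permutation-importance null uses 5 shuffles (protocol value): per-band
  75 % quantiles over 5 draws are coarse, which is part of why the
  amplitude-matched default matters on easy tasks.
* SPA's exhaustive start-column scan costs O(L²·max_vars) projections plus
  the CV scan; it is intended for a few hundred bands, not thousands.
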