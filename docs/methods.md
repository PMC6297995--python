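# Methods

`ctvlt` implements an adaptive-compression workflow for CT: estimate, for
each image, the visually lossless threshold (VLT) — the highest JPEG2000
compression ratio (CR) at which the compressed image remains visually
indistinguishable from its original — and compress to exactly that ratio.
Three estimation pathways are provided, together with the psychophysical
machinery that produces reference thresholds and a synthetic-data module
that makes the whole design testable without clinical images.

## The prediction model

The direct pathway is a multiple linear regression of the reader-panel
threshold `vlt_rad` on nine candidate predictors: five image features
computed on the window-mapped display raster (`image_sd`,
`image_entropy`, `percentage_lf`, `variation_hf`, `visual_complexity`)
and four DICOM header covariates (effective mAs, section thickness,
field of view, reconstruction filter as a binary soft-tissue /
medium-sharp indicator). Predictions are clamped to the CR search range
[2, 40] and flagged when clamped.

Variable selection is backward stepwise under the Gaussian
likelihood-ratio statistic, `n·ln(RSS_reduced/RSS_full)` against
χ²(df): removal at p > 0.10, re-entry at p < 0.05, ties broken toward
the variable later in the canonical candidate ordering. Every candidate
step must also pass a cross-validation guard: the mean 4-fold
out-of-fold RMSE (averaged over 5 seeded fold assignments to suppress
Monte-Carlo noise in the estimate) may not grow by more than 2%
(relative; `cv_tol`, configurable).

Cross-validation additionally acts as an active pruning stage. Pure
p-value backward elimination at α = 0.10 is known to retain at least
one noise covariate with substantial probability (with four spurious
candidates, roughly 1 − 0.9⁴ ≈ 35%, because the remove-largest-p rule
leaves behind exactly the covariates with accidentally small p-values).
Once LR elimination stalls, the procedure therefore keeps removing the
variable whose removal yields the lowest CV RMSE, as long as that RMSE
stays within the 2% tolerance of the current model's. A genuinely
predictive variable inflates the out-of-fold RMSE by roughly t²/(2n)
when dropped — about 13% for a partial |t| of 5 at n = 103 — and is
protected; a chance-correlated noise variable changes it by well under
the tolerance and is pruned. Fold assignment is a seeded shuffle, so
the entire selection is deterministic given (data, seed). If every
variable is removed the result is a flagged intercept-only model.

Predictors are not standardized (coefficients stay in natural units);
collinearity is monitored via the design-matrix condition number with a
logged warning above 10⁶. Fits use a numerically stable least-squares
solve; the test suite cross-checks coefficients against statsmodels and
an explicit normal-equations solve.

## The fidelity-metric pathway

The competing pathway never sees the covariates. A scalar cutoff is
calibrated on a training set: each training image is compressed to its
own `vlt_rad`, the metric is evaluated on the (original, compressed)
pair, and the cutoff is the arithmetic mean of those values. For a new
image, the estimated VLT is the largest CR whose fidelity still meets
the cutoff, found by bisection on log₁₀(CR): 14 halvings on [2, 40]
give a resolution below 0.01 log₁₀ units. Fidelity is non-increasing
in CR up to rate-control granularity (a tested property); the final
bracket is re-verified with three supplementary evaluations and
discrepancies are logged. Saturated searches return the range boundary
with an explicit flag, never silently. In practice the search
resolution is limited by the codec's ±5% rate-control tolerance rather
than by the bisection width.

Two metrics are registered. `psnr` is the universal
`10·log₁₀(peak²/MSE)` on HU rasters with peak 4095 (the 12-bit HU
container; configurable). `hvs` is a contrast-sensitivity-weighted SNR:
reference and error images are weighted in the frequency domain by the
Mannos–Kelly band-pass contrast sensitivity function (peak ≈ 8
cycles/degree; 64 samples/degree maps a 512-px section to a typical
diagnostic viewing geometry), and the score is the weighted
signal-to-error energy ratio in dB. It is a deliberately lightweight
stand-in for multi-stage visual-difference predictors; it exercises the
identical calibration/search pipeline, and the metric registry is
pluggable so a heavier model can be dropped in. Faithful reproduction
of any published multi-stage HVS model is out of scope.

## QUEST threshold measurement

Reference thresholds come from a Bayesian adaptive staircase on
log₁₀(CR), where psychometric behaviour is approximately additive. A
session is 25 forced-choice trials: trial one presents CR 5:1; each
later trial sits at the posterior mode (ties toward the lower grid
point); the final estimate is the posterior mean. The prior is a
truncated Gaussian, mean log₁₀ 5 and SD 0.5 log units, on a 200-point
grid spanning [log₁₀ 2, log₁₀ 40]. The assumed psychometric function
is a Weibull-shaped sigmoid in log-CR distance with its half-way point
at the threshold, floor at the false-alarm rate and ceiling at
1 − lapse. Placement-at-mode / estimate-at-mean is one standard QUEST
variant; both choices are exposed through the module API.

Simulated observers replace the reader panel: each has a true
threshold, slope 3.5, false-alarm 0.04 and lapse 0.02 (conventional
psychophysics values — simulation parameters, not claims about any
reader panel). A panel is 5 readers whose log-thresholds scatter around
an image's true VLT with SD 0.05 log₁₀ units; the image's `vlt_rad` is
the median of the per-reader estimates. Under these conditions 200
seeded sessions recover thresholds drawn in [4, 12] with a median
absolute log₁₀ error of ≈ 0.027 (the suite asserts < 0.06).

## JPEG2000 codec conventions

Irreversible 9/7 wavelet, 5 decomposition levels, single tile, one
quality layer per target rate (OpenJPEG via Pillow) — fixed and
recorded so codestreams are bit-reproducible. CR is defined on
uncompressed pixel-data bytes with the numerator fixed at
rows×cols×2 bytes regardless of stored bit depth, making ratios
comparable across images. HU pixels are shifted losslessly to unsigned
12-bit (HU + 1024) before encoding. The achieved CR must land within
±5% of target (rate control quantizes to packet boundaries); a target
below the codec's quality floor — where the most faithful encoding is
already smaller than requested — is returned flagged rather than
raising, since the fidelity search's lower bracket routinely sits
there. Lossless mode (reversible 5/3) backs the `visual_complexity`
feature.

## Image features

All five features are computed on the 8-bit display raster after the
clinical window (abdomen 20/400 HU, chest −600/1500 HU) — the
intensities under which thresholds are measured — not on raw HU.
Whether to use HU or display intensities is a genuine design choice;
the display-mapped convention is recorded as this package's, and each
feature sits behind its own function so alternatives can be swapped.
Definitions: population SD; Shannon entropy of the 256-bin histogram
(0–8 bits); share of blockwise 8×8 DCT AC energy with index sum
u+v ≤ 2 (a constant raster with zero AC energy returns 0 by
convention); RMS of the one-level Haar HH subband (the subband is
zero-mean by construction, so this is its SD about zero); and lossless
JPEG2000 bytes over raw display bytes. Whole-image support is used — no
body masking.

## The synthetic corpus

The generator emulates a five-subset body-CT study: abdomen 4 mm and
2 mm (soft-tissue kernel), chest 3 mm and 2 mm (medium-sharp), and
low-dose chest 3 mm (medium-sharp, 22–31 effective mAs), with subset
counts 42/42/41/41/40 (206 images), covariates drawn uniformly from the
per-subset ranges, and a 512×512 matrix whose elliptical body fills the
FOV (the FOV is matched to body diameter). Quantum noise is Gaussian
with SD = 265/√(mAs·mm) HU — about 12 HU for a 120-mAs, 4-mm abdomen
section, typical of soft-tissue kernels — and the reconstruction kernel
shapes the noise texture: a mild Gaussian blur for soft-tissue, a mild
unsharp mask for medium-sharp.

Patient-to-patient content is randomized aggressively (body aspect and
fat thickness, organ sizes and attenuation, contrast phase, bowel gas,
lung volume and vessel density, soft-tissue texture amplitude). This is
deliberate: with near-deterministic content the image features separate
body part almost perfectly, and since the reconstruction filter is
confounded with body part across the five subsets, neither the filter
indicator nor the feature coefficients would be statistically
identifiable. Real corpora show wide within-protocol variation in image
statistics; the randomization emulates that, and it is what gives every
predictor usable partial variation.

Ground-truth VLTs come from a known linear model over the five
informative variables (st +0.55, effective mAs +0.013, filter_sharp
+6.5, visual_complexity −25, variation_hf +0.55; intercept 8, noise SD
0.5, clipped to [2, 40]). Signs: thicker and higher-dose sections are
smoother and more compressible; structurally complex images expose
artifacts; high-frequency content masks them. Magnitudes were set
against each predictor's *partial* (within-protocol) SD in the phantom
corpus so that every variable carries partial |t| ≈ 5–8 at n = 103 —
individual coefficients are large because the protocol-level
collinearity leaves only modest independent variation per variable,
while subset-mean contrasts stay moderate (thick > thin within each
body part, standard-dose chest > low-dose chest, means ≈ 6–10).

What the generator does *not* emulate: anatomy realistic enough for
reading, pathology, scanner-specific noise correlations, and — most
importantly — any causal link between the distortion-vs-CR curve of an
image and its true VLT. The synthetic truth is the linear model, so on
this corpus the regression pathway is expected to dominate, and the
calibrated PSNR/HVS pathway agrees poorly with `vlt_rad` (its search
machinery is instead validated directly against an exhaustive-scan
oracle and a calibration-consistency construction). Passing tests
demonstrate that each pipeline stage is implemented correctly and that
the study design closes end to end; they do not demonstrate clinical
performance on real CT.

## Problem sizes and numerical choices

The test suite runs the study at its design scale where that is cheap
(206 phantoms at 512×512 for the end-to-end closure; a rendered
103-image training corpus with 100 response-noise replicates for
selection recovery; 200 QUEST sessions) and at 256×256 for the
codec-heavy searches (50 phantoms for the bisection-vs-grid oracle, 10
for calibration consistency), a size at which one compress–decode–
measure cycle costs ~40 ms. Agreement tolerances: one 0.05-log₁₀ grid
step for the search oracle; the codec's 5% rate-control tolerance for
calibration consistency; 0.7 CR units for the end-to-end mean
|VLT_true − VLT_model| (generative noise E|ε| ≈ 0.40 plus estimation
overhead). Degenerate inputs have documented conventions: zero-AC
rasters → `percentage_lf` 0; identical image pairs → infinite fidelity
sentinel; zero-variance repeated-measures input → (F = 0, p = 1);
empty stepwise survivor set → flagged intercept-only model.

## Statistics

Agreement between a prediction method and the reader reference is
reported as the mean absolute difference with a t-based 95% CI,
ICC(2,1) — two-way random effects, absolute agreement, single rater
(the conservative standard for a fixed panel; the consistency form is a
switch away) with the McGraw–Wong F-based CI — and Bland–Altman bias
with 1.96·SD limits of agreement. Methods are compared with a one-way
repeated-measures ANOVA on per-image absolute errors (uncorrected F;
no sphericity correction is applied, which is logged as a caveat) with
Bonferroni-corrected paired-t post-hocs. The sample-size utility
returns the smallest n with t₍₁₋α/₂,ₙ₋₁₎·sd/√n below a target CI
half-width — 103 at sd 0.51 and half-width 0.10 — and a companion
utility reproduces the preliminary repeated-split SD estimation that
motivates such a calculation. ICC and the repeated-measures F are
computed from the classical mean-squares decompositions (pingouin
cross-checks them in the tests; the direct array path keeps the
1000-replicate type-I simulation fast).

## Known limitations

* The five feature definitions are reasonable reconstructions of the
  named concepts, not replicas of any particular prior implementation.
* The `hvs` metric is a single-stage CSF-weighted SNR, far simpler than
  multi-stage visual-difference predictors.
* The filter/body-part confound in the five-subset design means the
  filter coefficient is identified only through within-protocol feature
  variation; on a corpus without such variation it is not estimable.
* GSDF display calibration is not modelled; windowing is plain linear
  (features and metrics operate on window-mapped intensities; display
  hardware affects only luminance).
* DICOM support covers single-frame CT objects only.
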