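# Methods

This note records the models, conventions and design choices behind
`saltspec`, stage by stage, including the points where the underlying
procedure is under-specified and a concrete choice had to be made.

## Imaging model and flat-field correction

A sample is a set of 2-D band images over the controlled vocabulary
{F440, F520, F690, F740} ∪ {R460 … R910}. Raw digital numbers are stored as
16-bit unsigned TIFF pages (bit depth of the CMOS output is not documented;
16-bit is assumed), corrected percent-scale images as 32-bit float pages,
both with a JSON sidecar naming bands, exposures and pot/view/period/class.
Pixel coordinates are row-major with the origin at top-left throughout.

Correction is `R = (S − D)/(W − D) × 100 %` per band, clipped below at zero.
Pixels where the reference dynamic `W − D` is non-positive are set to zero
and tallied (`meta['invalid_px']`) rather than interpolated — simpler and
auditable. The correction is scale-invariant (any common gain on S, W, D
cancels) and monotone in S; both properties are regression-tested. The
illumination-uniformity audit reports the coefficient of variation as
100·sd/mean with the population (n) standard deviation; n vs. n−1 is not
documented and the difference is immaterial at full-frame pixel counts.
Whether fluorescence bands should be exposure-normalized before ratioing is
likewise undocumented (exposures differ: 350/250/100/100 ms); a
`normalize_by_exposure` config flag exists and defaults to off.

Plant segmentation runs on corrected F740: Otsu's threshold, largest
connected component, hole fill. Otsu is the standard parameter-free choice
where only "a mask from F740" is specified; an exhaustive
between-class-variance search is kept as an independent oracle in the tests.

## Feature definitions

All per-plant scalars are computed on masked band **means** (ratio of means,
not mean of per-pixel ratios): the per-plant mean is the reported quantity,
and the ratio-of-means is stable where per-pixel ratios amplify noise. The
per-pixel index images used in the fused stack divide with an ε-guard
(ε = 10⁻⁶ of the denominator's masked mean) and count guarded pixels in a
saturation tally.

The blue reference band for GR/PSRI/NDVI is R460: the index formulas cite
450 nm but the platform has no 450 nm LED, so the hardware constrains the
choice. The NIR reference is R780. GR is implemented with denominator
(2·R_R + R_G + R_B) exactly as printed; the common green-leaf-index reading
(2·R_G + R_R + R_B) is available via `gr_variant="green_leaf_index"`.

The scalar feature table carries 3 fluorescence means, 3 fluorescence
ratios, 11 reflectance means, GR, PSRI, NDVI and all 55 SR scalars — 75
features. The fused image stack carries 30 channels in a fixed, regression-
tested order: [F520, F690, F740], the 3 ratio images, the 11 reflectance
bands in wavelength order, [GR, PSRI], and the 11 selected SR images. NDVI
stays in the scalar table but out of the stack: unlike GR and PSRI it does
not separate the classes.

## ReliefF and the SR subset

The Relief variant is a deterministic full-pass ReliefF: every one of the m
instances is visited once; its k = 10 nearest hits and k nearest misses
(Euclidean distance on min-max-normalized features) contribute
`Σ diff(f, x, miss)/(m·k) − Σ diff(f, x, hit)/(m·k)` to each feature weight.
Determinism (no instance sampling) makes the weights reproducible and
testable against a hand-traced 4-point oracle. Per period, the top-5 SR
indices by weight are taken (ties broken by name) and the three periods'
selections are unioned; on the reference weight tables this yields exactly
the 11-parameter subset used downstream. On synthetic data the union's size
can differ from 11, so the pipeline adjusts to exactly 11 channels by each
feature's best weight across periods — the fused stack needs a fixed
channel inventory.

The scalar inventory here sums to 75 features against a reported total of
79; the exact reported inventory is not itemized anywhere, so the
discrepancy is recorded rather than resolved. Nothing downstream depends on
it: selection operates on the 55 SR columns and the stack on the 30-channel
list.

## Cube PCA and score images

The 30-channel stack of every training sample is unfolded to a
(masked pixels × 30) matrix; pixels from **all** training samples are pooled
and the channels z-scored before a single global decomposition. A pooled
(dataset-level) fit is required because the OB stem allocation needs one
dataset-level explained-variance vector; a per-sample fit could not supply
it. The implementation accumulates first and second moments in a streaming
pass and eigendecomposes the pooled correlation matrix, which equals PCA on
the pooled z-scored matrix (cross-checked against an SVD oracle at 1e-9)
while holding arbitrarily many stacks in constant memory.

Component signs are fixed by making each loading's largest-magnitude entry
positive (the decomposition is sign-ambiguous; a convention is needed for
reproducibility). Zero-variance channels are dropped with a warning.
Standardization statistics always come from the training split; validation
samples are transformed with frozen statistics. The retained count r is the
smallest with cumulative explained variance ≥ 0.95 (capped at 9 in the
pipeline, matching the 9-score-image operating regime); score vectors fold
back to r images per sample, zero outside the mask.

## Network architecture and the parameter audit

The baseline is the published EfficientNet-B0: a 3×3/stride-2 stem of 32
kernels, seven MBConv stages (expansion 1 or 6, squeeze-excitation at 1/4 of
the block input, kernel 3 or 5), a 1280-wide 1×1 head, Swish activations.
Variants scale widths by β^φ with divisor-8 rounding and repeats by
⌈α^φ·r⌉; the variant table used is B0 (1.0, 1.0, 224), B2 (1.1, 1.2, 260)
and B4 (1.4, 1.8, 388) — the B4 resolution follows the comparison table used
downstream even where 388 differs from the more common 380. No architecture
search is performed; the stage configuration is taken as given.

`count_learnable_parameters` totals an auditable manifest per category.
Strict learnables (conv/dense weights, biases, batch-norm scale and offset)
of the 3-channel, 2-class B0 come to 4,010,110 — consistent with the
canonical 5,288,548 under a 1000-class head. The published figure of
4,031,118 exceeds this by exactly the total number of batch-norm features
(21,008), i.e. it counts one per-channel running-statistics vector as
learnable; `include_bn_stat_sets` (0/1/2) reproduces either convention, and
the per-category breakdown makes the offset diagnosable at a glance. The
affine input-channel law Δ = (n−3)×3×3×32 holds exactly by construction and
is asserted for n = 4…9.

The OB input block splits the input into single-channel planes; channel i
gets its own bank of 3×3×1 stride-2 kernels, with bank sizes apportioned to
the channels' variance contributions by largest remainder over renormalized
shares, a floor of one kernel per channel, surplus by descending fractional
remainder and ties toward the lower channel index. Remainders are measured
against the post-floor provisional counts, which keeps the allocation
monotone in the shares (measuring them against the raw floors does not).
Banks concatenate to the stem width, so the OB stem's total convolution
weights are 3×3×stem_width regardless of channel count, followed by **one
shared** batch-norm and Swish — per-bank normalization was rejected to keep
parameter parity with the baseline stem, and everything downstream is
byte-identical to the baseline. Whether activation applies per bank or after
concatenation is not documented; shared post-concatenation is chosen.

Training uses cross-entropy with Adam. The mini-batch default is 64 (the
value in the model-comparison table); 128, the value given in the methods
text, is available via config — the two printed values conflict. The
learning rate is 0.01. Augmentation applies, with one transform shared by
all channels and fully seeded: independent horizontal/vertical flips
(p = 0.5 each), an isotropic scale drawn uniformly from [0.75, 1.25]
(re-drawn a bounded number of times if the scaled plant would leave the
frame), and a translation keeping the plant's bounding box inside the frame.
The best-validation checkpoint (parameters **and** batch-norm running
statistics) is retained; no stopping rule beyond an optional
validation-accuracy threshold, since only epoch-indexed bests are reported.

Two execution profiles exist. The *full* profile is audit-grade: the exact
scaled architecture as a parameter manifest (the MBConv trunk is specified
and counted, not executed). The *desk* profile is a compact runnable network
— OB or ordinary stem (default width 16 in the pipeline, so the allocation
is non-trivial at 9 input channels), one 16-wide 3×3/stride-2 stage, global
average pooling, linear head — implemented in numpy with manual
backpropagation and verified against central finite differences at 1e-4.
Parameter-law assertions always run on the full manifest, never on the desk
trunk. Grad-CAM takes the gradient of a class score at the last
convolutional map, spatially averages it into channel weights, rectifies the
weighted activation sum, bilinearly upsamples to the input resolution and
max-normalizes to [0, 1]; a single-conv toy model gives a closed-form
reference map.

## Splitting and metrics

The experimental unit is the pot; all views and periods of a pot stay on one
side of the split, and the trainer refuses pot overlap outright. The
stratified 152-of-203 split holds out 26 control and 25 salt pots — the only
integer composition of the 51 validation pots consistent with the 102:101
class ratio and with every reported per-class accuracy row; it is a derived
reconstruction, not a documented quantity. Per period that is 104 control
and 100 salt validation images.

Metrics treat salt-stressed as the positive class (uniquely consistent with
every reported row: e.g. day 5, tp = 81, fp = 12 gives precision 87.10 %).
`confusion_from_class_accuracies` inverts per-class accuracies and class
sizes into integer confusion counts (rounding tolerance 0.5) so every
reported accuracy/precision/F1 row is recomputed, at 2-decimal percentages
and 3-decimal F1, from first principles. The classical KNN/SVM/RF baselines
are standard scikit-learn estimators on z-scored scalar features behind the
same pot-disjoint guard.

## Synthetic scenes: what they emulate, and what they do not

A scene is a union of 3–6 random ellipses ("leaves") on a background, imaged
through a radial vignette (corner/center = 1 − strength, default 0.25) with
multiplicative Gaussian noise (default sd 3 % of signal, switchable to
additive). A band's true leaf signal is a percent-of-reference level t and
the raw digital numbers are S = D + (t/100)·(W − D)·(1 + noise), so
flat-field correction provably removes the injected vignette. White frames
are a vignetted flat at 30,000 DN, dark frames 100 DN, both lightly noisy.

The class-effect table multiplies the leaf signal per band and period. The
reported effect magnitudes pin the F520/F690 ratio factors (1.085 at day 10,
1.192 at day 17, via F690 falling to 0.90/0.80 of control and F520 set to
the product); the remaining factors encode only reported directions — green
and yellow reflectance down, 780–910 nm reflectance up, hence GR down and
PSRI up — and bands without a reported effect keep factor 1. Pot counts
default to 102 control + 101 salt, 4 views, periods {5, 10, 17}. Frames
default to 96×96 px (the spatial scale of the real 1920×1200 frames is not a
modeled condition); tests use 32–48 px frames, and the surrogate study runs
60 pots at 48 px with the desk network — problem sizes chosen so the whole
chain runs comfortably on one CPU.

What passing the surrogate does **not** show: the generator has no botanical
realism (no leaf venation, overlap occlusion, specularity or canopy
geometry), its class separation is by construction stronger and cleaner than
real day-5 physiology, and the desk network is far smaller than the scaled
variants. Synthetic validation accuracy therefore demonstrates that the
pipeline's stages compose correctly and that the OB stem can learn
variance-ranked score images — not that any particular field accuracy is
attainable. The reported validation accuracies on the real images
(84.80/91.18/95.10 %) are covered instead by exact reproduction of their
metric arithmetic.

## Numerical conventions

- Population (ddof = 0) standard deviations throughout standardization.
- PCA loading signs: largest-magnitude entry positive.
- ReliefF ties (equal weights) break by feature-name order; allocation ties
  by lower channel index.
- ε-guarded divisions carry a saturation tally instead of inf/nan.
- Feature tables round-trip CSV at ≤ 1e-12 relative error; integer images
  round-trip TIFF bit-identically.
- All randomness flows from explicit integer seeds (generation keys derive
  per-sample streams from the dataset seed and the sample identifiers, so a
  sample is reproducible in isolation).
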