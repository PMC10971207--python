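# Methods

## Problem and scope

The package segments unstained oral-mucosa tissue sections into three
classes — non-epithelium (connective tissue / stroma), dysplastic epithelium
and non-dysplastic epithelium — from label-free imaging: three
discrete-frequency IR absorbance bands plus a darkfield visible image.
Physical acquisition (instrument control, transflection optics,
deparaffinization), H&E staining and pathologist annotation are out of
scope; the package starts from rasters and a per-pixel ground-truth label
map. Because no clinical dataset ships with the package, a synthetic
tissue-phantom generator is a first-class module: it defines the study
conditions under which the pipeline is tested.

## Band-ratio normalization

Raw absorbance at band b is modelled as A_b(x) = t(x) · µ_{c(x),b} · ε(x):
a class-dependent chemical level µ modulated by a smooth multiplicative
thickness/density field t and noise. Dividing the 1238 and 1546 cm⁻¹ bands
by the Amide I band (1658 cm⁻¹) cancels t exactly, which is the entire point
of the normalization; the two ratio channels r₁₂₃₈, r₁₅₄₆ plus darkfield form
the analysis stack. Numerical guards: pixels with A₁₆₅₈ < 10⁻³ AU are
removed from the tissue mask rather than divided (the ratio there amplifies
detector noise), and ratios are clipped to [0, 3] to bound outlier leverage.
Ratio arithmetic is done in float64 so that multiplying all bands by an
arbitrary positive field changes the ratios by < 10⁻¹².

The plain per-pixel-ratio reading of "normalized to the Amide I image" was
adopted over a regression-based normalization; it is the only reading under
which the normalization cancels a multiplicative thickness field exactly.

## Grid conventions

Rasters are row-major and 0-based with the grid origin at pixel centers:
pixel (i, j) at pitch s sits at ((i+0.5)s, (j+0.5)s) µm. Resampling to the
common 1 µm grid preserves physical extent; intensities are interpolated
bilinearly, labels and masks by nearest neighbour (ties at exact half-pixel
distances resolve by round-half-to-even, numpy's rounding). Registration is
integer-pixel cross-correlation via FFT — sufficient because the phantom
channels are generated co-registered and the contract only requires exact
recovery of integer shifts; subpixel refinement is out of scope. The tissue
mask is Otsu's threshold on the Amide I band (the strongest, most uniform
tissue band), with holes under 64 px filled.

## Phantom design

Each section (default 1024 × 1024 µm at the 1 µm label grid) contains a
background margin, an epithelial band and underlying stroma. The
epithelium–stroma boundary is a sinusoid (default amplitude 60 px, period
200 px) with random phase plus 30 % low-frequency jitter — the simplest
shape producing rete-peg-like protrusions and hence realistic
boundary-confusion errors. One contiguous dysplastic focus (default 40 % of
the width) mimics lesion contiguity; tissue covers 85 % of the frame.

IR bands render at 2 µm/pixel as t · µ_{c,b} · exp(σ_{c,b} z(x)) + noise:

* t — log-normal thickness field, mean 1, correlation length 100 µm,
  CoV 0.15, shared bit-for-bit across the three bands;
* µ ratios (medians of A_b/A₁₆₅₈) encode the class orderings reported for
  real tissue: at 1238 cm⁻¹ non-epithelium (0.75) > dysplastic (0.60) >
  non-dysplastic (0.48) — dysplasia carries more nucleic acid; at 1546 cm⁻¹
  non-epithelium (0.85) > both epithelium classes (0.55 / 0.52);
* σ — class-conditional log-normal spread of the ratio (a ~4 µm-scale
  biochemical texture field): widest for non-epithelium in both bands
  (heterogeneous connective tissue), and at 1546 cm⁻¹ wider for
  non-dysplastic (0.07) than dysplastic (0.04) epithelium;
* additive detector noise, SD 0.01 AU.

"Noise-free" phantoms (`PhantomParams.noise_free()`) zero both the detector
noise and the within-class spread σ, leaving the thickness field in place —
this is the regime in which the per-class band ratio is exactly constant and
the normalization's cancellation can be asserted to machine precision.

Darkfield renders at 0.5 µm/pixel — deliberately finer than the IR grid so
the down-sampling path is exercised — as per-class base scattering intensity
plus Poisson-count nuclear speckle blurred to a 0.7 µm point-spread width.
Stroma has low base intensity (0.25) and sparse nuclei; both epithelium
classes share the same base intensity (0.45) and differ only moderately in
nuclear density (0.004 vs 0.003 nuclei/µm², dysplastic denser). This
confines reliable class-2/class-3 contrast to the IR channels by design: the
darkfield-only model can separate epithelium from stroma morphologically but
largely confuses the two epithelium grades, which is the regime the modality
ablation is meant to probe.

What the phantoms do **not** emulate: Mie scattering and dispersion
artifacts, standing-wave effects of transflection optics, realistic nuclear
morphology and chromatin texture, annotation noise, and inter-patient
variability. Passing tests on phantoms therefore validate the pipeline's
mechanics and the relative value of the modalities under the stated
assumptions — not clinical accuracy.

## Patch dataset

Non-overlapping tiles anchored at (0,0), row-major; partial edge tiles are
discarded (padding is not part of the tiling contract). A tile is retained
when ≥ 50 % of its pixels are inside the *tissue mask* — the mask, not the
annotation, because the mask is what exists before annotation in deployment.
Splits are by whole section; the default is a three-way train/val/test split
to keep early stopping honest, with a two-way design (held-out sections
serving both validation and blind testing) available via `two_way_split`. Per-channel
standardization statistics are computed over masked pixels of the training
sections only and travel with the model; held-out sections are standardized
with the stored values, never re-estimated.

## Network and training

`specseg.nn` implements the required layers and their backward passes in
NumPy (im2col convolutions over BLAS matmuls). Two backbones sit behind one
interface:

* `resnet50` — the standard 50-layer bottleneck residual network
  (stage widths 256/512/1024/2048, output stride 32, ~33 M parameters) with
  an FCN head, matching the architecture used on real tissue;
* `reduced` — a residual FCN for CPU desk-scale work: three stride-2
  conv-BN-ReLU stages (12/24/24 channels), two residual blocks at stride 8,
  a 1 × 1 classifier, nearest-neighbour upsampling, and a full-resolution
  3 × 3 refinement convolution that sees the raw input channels alongside
  the upsampled logits (residual form). The refinement restores boundary
  detail that the coarse stride otherwise quantizes away, at negligible
  cost; it is what lets the small network both memorize single patches and
  segment peg boundaries cleanly.

Training fixes the protocol: Adam (lr 2 × 10⁻⁴, weight decay 10⁻⁵,
L2-coupled), cross-entropy over tissue pixels only (background and
out-of-mask pixels contribute neither loss nor gradient), step LR schedule
lr(e) = 2 × 10⁻⁴ · 0.5^⌊e/5⌋, random affine augmentation of every patch each
iteration (rotation ± 30°, translation ≤ 10 %, scale 0.9–1.1, shear ± 5°;
channels bilinear, labels/mask nearest with the identical transform,
exposed regions filled with background), early stopping on validation loss
(patience 10, min-delta 10⁻⁴ by default), best-validation weights retained,
and n replicates seeded seed, seed+1, … Replicate metrics are aggregated as
mean and population SD (n divisor). Batch size (8), epoch budget and
augmentation magnitudes are declared defaults, not inherited constants.
Backbones initialize randomly (He); no pretraining is used.

Right-angle affine draws are snapped to exact index permutations (matrix
entries within 10⁻⁹ of an integer are rounded) so that a 90° rotation never
leaks edge pixels out of frame through floating-point fuzz.

Whole-section inference tiles the stack (default tile 256, overlap 32),
averages per-tile softmax probabilities where tiles overlap, argmaxes, and
forces non-tissue pixels to background. The last tile in each direction is
clamped to the section edge.

## Evaluation conventions

Metrics are computed over pixels inside the tissue mask with a tissue-class
ground-truth label; background never enters. "Accuracy" is overall pixel
accuracy (trace over total). F1 is macro-averaged across the three tissue
classes — chosen because it refuses to hide failure on the minority
dysplastic class, which is the clinically critical one; classes absent from
the truth are excluded from the macro mean and flagged. Confusion matrices
are row-normalized to percentages; rows with zero truth pixels are flagged
rather than divided.

## Problem sizes

Desk-scale defaults used by the test suite and the acceptance script:
12 sections of 1024 × 1024 µm, a 6/3/3 section split, 128 × 128 patches,
the `reduced` backbone, 3 replicates, and a 5-epoch budget with early
stopping — sizes chosen so a complete three-modality ablation is a
single-CPU job of a few minutes while still containing ~2.7 M held-out
tissue pixels. The real-tissue protocol (23 sections, 256 × 256 patches,
ResNet-50) is fully expressible through the same configuration surface.

## Known limitations

* The NumPy networks are CPU-bound; the `resnet50` backbone is functional
  and tested for contracts, but training it at full scale is impractical
  without accelerator support.
* Registration is integer-pixel; subpixel misalignment is not modelled (the
  phantom generator emits co-registered channels).
* Simple channel concatenation is the only fusion mechanism, consistent
  with the reference workflow; modality-specific fusion architectures are
  out of scope.
* The phantom's class appearance model is piecewise-stationary; it does not
  model gradual dysplasia grades or transitional epithelium.
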