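# Methods

This note records the models, parameter choices and numerical conventions
behind `phasefluct`, and what the synthetic experiments do and do not
demonstrate.

## Holographic reconstruction

An off-axis interferogram is modelled as
`I = 1 + v·cos(2π f_c · r + φ)` with carrier `f_c` (cycles/pixel) and sample
phase `φ = 2π·OPD/λ`. Reconstruction crops a disk around the carrier lobe of
`FFT(I)`, recenters it, inverse-transforms, unwraps the phase argument and
scales by `λ/2π`.

* **Crop radius.** Default: half the carrier-to-DC distance, capped at the
  margin to the Nyquist edge — the largest bandwidth that cannot leak DC
  energy. A crop radius that reaches the DC term is rejected
  (`CarrierOverlapError`).
* **Unwrapping** uses the reliability-sorted 2D algorithm from
  scikit-image. The output is congruent to the input modulo 2π per pixel
  and defined up to one global 2π multiple.
* **Piston.** The background region is everything below 20% of the map's
  dynamic range; its *median* is subtracted. The median is robust to cell
  tails that spill into the thresholded background, which biased a mean-based
  estimate by several nm on bump-shaped test objects.
* **Validity.** The sample phase gradient must stay below π/pixel;
  `simulate_hologram` enforces this precondition. Reconstruction is accurate
  to ~1e-4 % RMSE for band-limited fields; maps with sharp frame-edge
  discontinuities incur Gibbs ringing at the border (a property of the
  non-periodic DFT, not of the algorithm).
* **Standardization.** Frames are resized bilinearly (Gaussian anti-aliasing
  prefilter when downscaling, which keeps means within well under 1%);
  the working resolution default is 250×250.

## Fluctuation pipeline

* **Mask.** A disk at the centroid of the thresholded cell support
  (threshold 0.2 of the frame maximum), radius 0.7 of the support's
  equivalent radius `sqrt(area/π)`, shrunk if needed to stay strictly inside
  the frame, minimum 100 pixels. Eroding below the support radius excludes
  the cell edge, where vibrations are elevated.
* **PSD.** Outside-mask pixels are zero-filled (no apodization window); the
  temporal mean frame is subtracted; a full 3D DFT is taken. Total spectral
  power is checked against `N·Σ signal²` (Parseval) to 1e-6 relative before
  any binning. Power is divided by the number of masked pixels: raw DFT
  power scales with the analyzed area, and without this normalization a
  cell-size difference between groups can mask a genuine amplitude
  difference. Per-pixel PSD units make maps comparable across cells.
* **Temporal folding.** Rows cover ω in (0, Nyquist]; each row is the
  average of the +ω and −ω planes (identical radial averages for real
  input), keeping the self-conjugate Nyquist row on the same scale. The
  ω = 0 plane is identically zero after mean subtraction and is dropped.
* **Radial binning.** `floor(min(H,W)/2)` annuli of equal width spanning
  radius 0 to the spectral corner, so every pixel lands in exactly one bin
  and count-weighted means conserve the total exactly. Bins with no pixels
  are NaN and dropped from the q axis. Bin centers are reported in
  cycles/pixel, or 1/µm when a pixel size is attached.
* **Classifier scaling.** The PSD spans many decades, so classifier inputs
  use `log10(power + 1e-1)` clipped to the fixed range [−1, 9] decades and
  mapped to [0, 1] (`log_scale_map`). A per-map min–max was evaluated and
  rejected: it removes the absolute power level, which *is* the stiffness
  signal — with per-map scaling a fluctuations-only classifier performed at
  chance on synthetic data, with the fixed scale it reaches ~0.9 accuracy.
  `classifier_map` retains per-map scaling purely for display.

## Summary statistics

Per cell: `mean_opd` (arithmetic mean OPD over the mask) and
`mean_abs_fluct` (mean |entry| of the raw fluctuation map). Group
comparison: Welch's t-test by default (robust to unequal variances),
Mann–Whitney U as a rank-based option; two degenerate identical groups give
p = 1. No multiple-testing correction — only two summaries are compared.

## Architectures

Backbones end in global average pooling:

| backbone | feature length | default input | role |
|---|---|---|---|
| `resnet50-style` | 2048 | 64×64 | 50-layer bottleneck residual network |
| `small-cnn` | 128 | 16×16 | 3 conv-BN-ReLU blocks; CPU-fast test backbone |

Inputs: morphology maps are min–max normalized per image (phase offsets are
uninformative), fluctuation maps use the fixed log scale above; both are
resized to the backbone input size, and 1-/2-channel images are adapted to
the 3-channel stem (replication; third channel = mean of two). The head is
`[fused → 256 → 2]` with ReLU between, ending in a softmax. Fusion rules:
`fuse_double = concat(v_morph, v_fluct)`;
`fuse_triple = concat(v_morph + v_2ch, v_fluct + v_2ch)`, which reduces
exactly to `fuse_double` when the 2-channel feature vector is zero. The
`pretrained` flag falls back to seeded random initialization with a warning
when no weights file is available.

The NN core is NumPy throughout (im2col convolutions, batch norm with
running statistics, Adam), float32, single-threaded and bitwise
deterministic for fixed seeds. Max-pool ties break to the first (row-major)
element.

## Training and evaluation protocol

* Shuffles: independent random 60/20/20 splits; train/validation sizes use
  round-half-up, the remainder is test (216 cells → 130/43/43; 10 → 6/2/2).
  Unstratified by default; a stratified option exists and is advisable below
  ~20 cells, where an unstratified test split can miss a class.
* `TrainConfig` defaults are cross-entropy, batch 8, Adam at 2e-6,
  100 epochs — the regime of fine-tuning a large pretrained backbone. The
  synthetic protocol below trains the small backbone from scratch and passes
  1e-3 explicitly; 2e-6 barely moves a freshly initialized network within
  30 epochs.
* The checkpoint with the highest validation accuracy is kept (ties: lower
  validation loss, then the earlier epoch); per-epoch train/validation
  curves are recorded.
* Metrics with metastatic as positive: accuracy, sensitivity TP/(TP+FN),
  specificity TN/(TN+FP), precision TP/(TP+FP) (NaN when no positive
  predictions), and rank-based ROC AUC of the positive-class probability
  (equal to the Mann–Whitney U statistic over n₊·n₋). Aggregation is the
  mean and sample std (n−1) across shuffles.

## Synthetic data

Each cell is a truncated-paraboloid dome (static morphology) plus a
stationary Gaussian fluctuation field synthesized by spectral shaping of
white noise: amplitude `∝ max(q,1)^(−a/2) · max(ω,1)^(−b/2)` in the 3D DFT
domain, zero temporal-mean, RMS-normalized inside the cell interior,
multiplied by `edge_boost` in the outer 20% annulus of the dome and zero
outside, with white detection noise everywhere. Defaults emulate 4 s at
500 frames/s scaled to 64×64×256 for CPU-scale work.

Class-conditional parameters (mean ± sd per cell; 64 px frame):

| parameter | primary | metastatic | rationale |
|---|---|---|---|
| RMS fluctuation (nm) | lognormal, median 3 | lognormal, median 6 | softer metastatic cells; 2× amplitude ratio |
| dome radius (px) | 19.5 ± 2.75 | 15.5 ± 2.75 | metastatic cells smaller; overlap puts morphology-only accuracy in the mid-80s %, leaving measurable headroom for fusion |
| dome peak (nm) | 300 ± 30 | 330 ± 30 | smaller suspended cells round up taller |
| slopes a, b | 2.0 ± 0.1, 1.0 ± 0.1 | same | common spectral shape with per-cell scatter; the class contrast is carried by amplitude, as a stiffness change would. (An earlier variant with class-dependent slopes silently cancelled the amplitude effect on the map mean, because RMS normalization concentrates steeper spectra into the dominant low-q bins.) |
| edge boost | 2.0 | 2.0 | elevated edge vibration |
| noise floor (nm) | 0.3 | 0.3 | camera/shot noise |

What the generator does **not** model: cell motility and shape change,
irregular (non-circular) outlines, internal organelle texture, dry-mass
dynamics, optical aberrations beyond piston, correlated detector noise, and
any true membrane-mechanics dispersion relation. Passing the synthetic
protocol therefore shows that the pipeline extracts and fuses
amplitude/spectrum differences correctly — it does not certify performance
on real recordings, whose class contrast may be weaker or differently
structured.

## Problem sizes and determinism

The scaled study conditions used by the tests and the acceptance script:
120 cells (60/class) of 64×64×256 frames, small-cnn backbone at 16×16
input, 5 shuffles × 30 epochs, 5 seeded repetitions for the
architecture-ordering comparison. Under these conditions the morphology-only
single path reaches ~0.82–0.89 mean accuracy and the triple path matches or
exceeds it in every repetition (~0.87–0.92), with fluctuations-only at
~0.9 — on synthetic data the fluctuation modality is deliberately
informative. Identical configs and seeds reproduce all reports byte-for-byte
on CPU; every CLI artifact carries a YAML sidecar with the config hash, seed
and package version.

## Known limitations

* The residual backbone trains impractically slowly in pure NumPy at full
  resolution; it is intended for architecture-faithful construction,
  parameter counting and inference-scale checks, while the small backbone
  carries the training experiments.
* Off-axis reconstruction assumes a clean two-beam interferogram; no
  aberration compensation, halo removal or autofocusing is attempted.
* The disk mask assumes a roughly convex, centered cell; strongly elongated
  cells would need a shape-adaptive mask.
* `fit_spatial_exponent` assumes a separable power law and a noise-free
  central q decade; a strong noise floor flattens the fit.
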