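# phasefluct

Label-free classification of live cancer cells from dynamic quantitative-phase
imaging. The package turns off-axis holographic video of a single cell into
two complementary representations — the optical-path-delay (OPD) morphology
map and a spatio-temporal **fluctuation map** — and classifies cells as
*primary* or *metastatic* with a family of CNN fusion architectures. It is
aimed at quantitative-phase imaging groups who record cells at hundreds of
frames per second and want a stiffness-sensitive, staining-free readout of
metastatic potential.

## Method

**Reconstruction.** An off-axis interferogram `I(x, y)` carries the complex
sample field on a spatial carrier. The OPD map follows from

```
OPD = unwrap( arg( IFFT( crop_and_recenter( FFT(I) ) ) ) ) · λ / 2π   [nm]
```

where the crop isolates one cross-correlation lobe of the spectrum and a
piston (background median) is subtracted.

**Fluctuation map.** For a video `h(x, y, t)` of `T` frames at rate `f_s`,
restricted to a disk mask that excludes the vibration-prone cell edge:

1. subtract the temporal mean frame,
2. take the 3D DFT and its squared magnitude (PSD, normalized per analyzed
   pixel),
3. for each temporal frequency `ω ∈ (0, f_s/2]`, radially average the spatial
   plane over annuli of spatial frequency `q`.

The result `P(ω, q)` summarizes membrane dynamics in one image per cell:
softer (more metastatic) cells show larger fluctuation power.

**Classification.** Each modality image feeds a convolutional backbone
truncated after global average pooling (feature vector `v`). Architectures:

* single path — one backbone on morphology, fluctuations, or their
  2-channel stack (early fusion);
* double path — `concat(v_morph, v_fluct)` (late fusion);
* triple path — `concat(v_morph + v_2ch, v_fluct + v_2ch)`, combining early
  and late fusion.

The fused vector passes through two fully connected layers into a 2-class
softmax (positive class = metastatic). Evaluation uses repeated random
shuffles (60/20/20 train/validation/test, best-validation epoch) and reports
accuracy, sensitivity, specificity, precision and AUC as mean ± std across
shuffles. The networks run on a small, fully deterministic NumPy
backpropagation core, so CPU runs reproduce bitwise.

Because the original cell recordings are not public, the package ships a
first-class synthetic generator: dome-shaped cells with stationary colored
fluctuation fields (`power ∝ q^-a ω^-b`), class-dependent amplitude (the
stiffness proxy), boosted edge vibration, and detection noise.

## Worked example

```
$ phasefluct simulate --n-per-class 20 --out data --seed 42 --frames 128 --size 64
$ phasefluct fluctmap --input data/manifest.csv --fps 500 --out fluct
$ phasefluct stats --manifest fluct/manifest.csv --out summary.csv
mean_abs_fluct: p = 0.000648
mean_opd_nm: p = 0.000182
wrote summary.csv (40 cells)
```

The two Welch p-values compare the per-cell summaries between classes: the
mean OPD over the cell area (morphology) and the mean absolute value of the
fluctuation map (stiffness proxy). Both differ strongly at n = 20 cells per
class, while the per-cell histograms still overlap — neither summary
separates the classes on its own, which is what motivates the classifier.

```
$ phasefluct train --manifest fluct/manifest.csv --model model.yaml \
      --out runs --n-shuffles 5 --epochs 20 --lr 1e-3 --seed 0
$ phasefluct evaluate --run runs --out report.csv
     metric     mean      std
   accuracy 0.750000 0.197642
sensitivity 0.893333 0.153478
specificity 0.693333 0.338625
  precision 0.750000 0.276385
        auc 0.900000 0.115470
```

with `model.yaml` selecting the triple-path model:

```yaml
variant: triple
inputs: [morphology, fluctuations, two_channel]
backbone: small-cnn
```

At this miniature scale (40 cells, 20 epochs) the triple-path model reaches
75% mean accuracy and 0.90 AUC over 5 shuffles; the full protocol below uses
120 cells and 30 epochs. Multi-stage runs can also be described in one YAML
config and executed with `phasefluct run pipeline.yaml`.

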