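# Methods

## The generative-neuron operator

A Self-ONN layer generalizes convolution by giving every connection a
learned truncated MacLaurin series. For input window value `x`, the
connection responds with `c + v₁x + v₂x² + … + v_q x^q`; per output/input
channel pair and kernel offset there is one coefficient per power, stored as
`q` stacked kernels of shape `(out, in, k, k)`, plus one bias per output
channel. The pool operator is summation and the constant of the series is
fixed at zero (MacLaurin form) — the bias plays that role once per output
channel. With `q = 1` the layer is exactly a zero-padded cross-correlation,
which anchors both the unit tests and the plain-U-Net equivalence check.

Two design constraints follow from the power terms:

- **Input range.** Powers of magnitudes above 1 explode, so every Self-ONN
  layer expects inputs in [−1, 1]. Images enter Self-ONN models scaled by
  `x/127.5 − 1`; inside the network each Self-ONN layer is followed by tanh,
  which restores the bound. Plain-conv models receive `x/255` instead.
- **Initialization.** Weights start uniform in
  `[−1/√(fan_in·q), +1/√(fan_in·q)]` per power, a variance-scaled range that
  keeps the summed series at unit scale regardless of q.

No normalization layers are used inside Self-ONN units: tanh already bounds
the activations, and extra affine normalization would fight the learned
series coefficients. Plain conv decoder units keep conv–BN–ReLU.

The residual blocks: `SelfONNResBlock` maps channels C → C/4 → C through a
3×3 then a 1×1 Self-ONN layer (tanh after each) and adds the input back;
`SelfONNConvResBlock` runs a 3×3→1×1 Self-ONN path in parallel with a plain
3×3 convolution on the original input and combines the two paths
elementwise (channel concatenation available behind a flag). Block
"expansion" is interpreted as channel expansion at unchanged spatial size —
the only reading under which the residual addition is well-formed.

## Architectures

Encoders follow the standard reference topologies (ResNet 18/50/101/152,
DenseNet 121/161/201) with classifier heads removed, exposing five feature
maps at strides 2–32; a five-stage `tiny` encoder (<100k parameters) exists
for desk-scale work. ImageNet weights can be loaded from a local file but
are never downloaded and never required by tests. Decoders: U-Net (five
upsample–concat–double-conv blocks), U-Net++ (nested dense skip grid), FPN
(lateral 1×1 projections, top-down merge, per-level prediction maps summed
at input size), and Self-ONN U-Net — the U-Net topology with every decoder
conv unit replaced by a tanh-activated Self-ONN layer (a bottleneck-only
variant is available behind a flag, since the narrative around where the
Self-ONN blocks sit admits both readings). Every model ends in a 1×1
two-channel head with SoftMax; foreground is channel 1, and mask prediction
takes the per-pixel argmax with exact ties resolved to background
(conservative for lesion calling).

### Reference configuration and the parameter-count calibration

The published complexity figures for the two flagship models are exact
trainable-parameter totals (20,622,065 for the ResNet18 variant; 49,546,289
for DenseNet201). The encoder totals are fixed by the reference topologies
(11,176,512 and 18,092,928 here, matching the standard implementations),
so the printed numbers constrain only the decoder: its Taylor order q and
the five decoder widths. Two checks pin the topology: the *difference*
between the two printed totals equals `9q·(2944·d₁ + 384·d₂ + 192·d₃)`
exactly at `q=3, d₁..₃ = 256/128/64` — the signature of a double-conv U-Net
decoder whose first (skip-facing) conv is a q=3 Self-ONN layer. The nominal
widths 256/128/64/32/16, however, overshoot both totals by the same 4,177
parameters, so the exact widths the totals encode differ slightly from the
usual powers of two. `calibrate_selfonn_unet` therefore solves the integer
constraint system directly: it enumerates (q, d₁..d₅) satisfying both
totals simultaneously, preferring q closest to 3 and then widths closest
(L1) to the nominal configuration. The search is deterministic and finds

    q = 3, decoder channels (256, 124, 72, 25, 33)

which reproduces **both** totals exactly; the acceptance script rebuilds
both full networks under this configuration and recounts every parameter
from the instantiated layers. The default configuration for new models
remains the nominal 256/128/64/32/16.

## Preprocessing

Voxels are clipped to the liver window [−100, 400] HU (idempotent) and
mapped linearly to [0, 255]; values stay real-valued by default, with an
optional uint8 mode rounding half away from zero. Volumes are cut along the
third array axis into axial slices (0-based indices); the liver mask is
labels ∈ {1, 2} and the tumor mask labels = 2, since tumor voxels are liver
tissue. Slices without liver can be dropped for stage-1 training (logged)
or kept; no resampling or reorientation is performed.

## Cascade

Stage 1 predicts the liver mask; the ROI is the elementwise product of
image and mask (`multiply` mode — a 2-channel `concat_channel` mode is
available, as the ROI construction is described both ways in the
literature); stage 2 predicts tumor on the ROI. During training the tumor
stage receives ground-truth liver ROIs; at inference it receives predicted
ones. An optional `constrain_tumor_to_liver` flag intersects the tumor mask
with the stage-1 mask (off by default — no post-hoc intersection is
assumed, and no inter-stage post-processing such as largest-component
selection is applied).

## Loss, metrics and aggregation

The training loss is soft dice with squared denominators on the foreground
probability channel, computed per sample and averaged over the batch so
small lesions are not drowned out by empty slices sharing the batch; a 1e-7
epsilon keeps empty/empty defined (loss → 0). Evaluation uses hard-mask
confusion counts: accuracy, IoU and DSC per slice; the DSC–IoU identity
`DSC = 2·IoU/(1+IoU)` is asserted to 1e-12 in tests. A slice with an empty
reference and an empty prediction scores dice 1 (configurable); a
prediction sharing no foreground pixel with a non-empty reference scores 0
and increments the zero-dice count. Reports aggregate per-slice values with
mean ± 1.96·SE over the pooled test slices (the grouping unit behind
published ± values is not specified; per-slice pooling is this package's
choice).

## Training protocol

Defaults follow the tabulated training setup: Adam (betas 0.9/0.999),
learning rate 1e-4, batch 8, at most 50 epochs, early stopping after 10
epochs without validation improvement, learning-rate drop by 0.2 after 6
stale epochs. Where the surrounding prose disagrees with the table (1e-3,
batch 16, 40 epochs, patience 5), the table wins; every value is
configurable. Both patience counters require the validation loss to improve
by at least `min_delta` (default 1e-4) to reset — without a threshold, the
slow drift of batch-norm running statistics registers as perpetual
"improvement" and defeats early stopping; the restored checkpoint still
tracks the strictly best validation loss. Cross-validation splits are by **volume**, never by slice:
a seeded shuffle, k rotating test blocks (~20%), and the last 20% (floor)
of each fold's remaining volumes as validation — 100 volumes at k=5 give
20/16/64 test/val/train. "Best model" means the lowest-validation-loss
checkpoint, restored before returning.

## Synthetic phantoms

Each phantom volume is a smooth random ellipse ("liver", base 50–70 HU)
whose axes wax and wane over a consecutive run of axial slices, with 0–3
spherical hypodense "tumors" (10–40 HU, radius 4–9 mm) placed strictly
inside the liver — placement uses a millimetre-space distance transform
with anisotropic voxels (1×1×2.5 mm), so tumors respect the thick-slice
geometry. Background sits at −80 HU and Gaussian noise (σ = 8 HU) is added
to the image only; labels stay noiseless. Volumes are bit-reproducible from
(seed, volume index) and export as LiTS-style `volume-i` /
`segmentation-i` NIfTI pairs with a manifest.

What the phantoms do *not* model: real anatomical shape variation,
neighbouring organs of similar attenuation, streak/beam-hardening
artifacts, contrast-phase effects, or ambiguous lesion boundaries. Passing
the phantom benchmarks therefore demonstrates that the machinery —
preprocessing, both training stages, the cascade and the metrics — is
correct and can learn, not that clinical-grade accuracy is reached on real
CT.

## Desk-scale experiment sizes

The end-to-end smoke experiment uses 4 phantom volumes of 12 slices at
64×64, a ~75k-parameter tiny Self-ONN U-Net per stage, batch 4, learning
rate 3e-3 (scaled up from the 1e-4 default in proportion to the greatly
reduced problem), and at most 120/200 optimizer steps for the liver/tumor
stages. Under these sizes the cascade reaches held-out liver DSC ≥ 0.99 and
tumor DSC ≈ 0.6–0.9 depending on seed, in about a minute per seed on one
CPU.

## Numerical notes and limitations

- All arithmetic is float64; forward/backward of every operation
  (convolution, Self-ONN, pooling, bilinear upsampling, batch norm,
  softmax) is validated against central finite differences.
- The vectorized Self-ONN forward shares its im2col core with conv; an
  intentionally naive nested-loop implementation serves as the independent
  oracle in tests.
- Bilinear upsampling uses the half-pixel-centre convention.
- Training is single-process CPU NumPy: appropriate for the tiny reference
  experiments, far too slow for full-scale clinical training runs.
- 3-D context is ignored by design (slice-by-slice 2-D segmentation);
  surface-distance metrics (HD95/ASSD) and fold ensembling are out of
  scope.
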