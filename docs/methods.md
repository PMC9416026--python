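# Methods

## Data model and calibration

A hyperspectral cube is `height × width × bands` reflectance with a
strictly increasing wavelength axis, an optional binary lesion mask
(1 = lesion) and an optional benign/malignant label. Reflectance comes from
flat-field calibration of raw counts against white and dark references,
R = (raw − dark)/(white − dark), clipped to [0, 2] to bound specular
artifacts (the cap keeps the subsequent affine map onto the generator's
tanh range well-defined). A zero `white − dark` anywhere is an error that
names the offending voxel.

The emulated camera covers 450–950 nm in 125 bands. We use a linear
125-sample grid; the nominal 8 nm spectral resolution quoted for such
instruments is inconsistent with 125 bands over a 500 nm span (4.03 nm
spacing), and the linear grid is the simplest self-consistent choice. The
first five and last four bands are noise-dominated and trimmed by default,
leaving 116 bands spanning ≈466–934 nm (half-open, 0-based trims).

Class labels are *smoothed* before use: malignant maps to a uniform draw in
[0.7, 1], benign to [0, 0.3]. Smoothing curbs discriminator overconfidence
and doubles as the conditioning scalar of the conditional GAN.

## Phantom generator

The phantom module emulates the statistical structure of a small clinical
HS lesion cohort (default 40 benign + 36 malignant cubes of 50 × 50 × 116;
tests shrink the geometry through `PhantomParams`):

- **Signatures.** Three smooth curves (healthy skin, benign, malignant)
  defined by control points and evaluated with a monotone-segment (PCHIP)
  spline, which cannot overshoot the control values, so signatures stay in
  [0, 1]. The shapes are qualitative skin optics — melanin darkens lesions
  below ~600 nm, an oxyhemoglobin-like trough at 540–580 nm is deepest for
  the malignant class, and all curves rise toward the near-infrared. The
  control points are package fixtures, not digitized measurements.
- **Masks.** A single connected elliptical blob with sinusoidal boundary
  perturbation, centered within the middle third of the frame; lesion
  fraction is kept in [0.05, 0.6] (re-drawn when a perturbation lands
  outside, ≤20 attempts, then the unperturbed ellipse).
- **Mixing.** Pixel spectrum = mask·lesion + (1−mask)·skin, scaled by a
  per-image mean-one log-normal amplitude jitter (illumination
  variability), plus i.i.d. Gaussian band noise (sd 0.02) and a 0.5 px
  spatial Gaussian blur; clipped to [0, 1].

Parameter defaults worth noting:

| parameter | default | rationale |
|---|---|---|
| `amplitude_jitter_sd` | 0.05 | the benign/malignant difference is largely multiplicative; 0.05 keeps mean lesion spectra linearly separable at ≥95% held-out accuracy, the level at which downstream protocol tests are informative |
| `noise_sd` | 0.02 | band-noise floor of a calibrated cube |
| `smoothness_sigma_px` | 0.5 | optical blur; also blends ~1 px of skin into lesion boundaries, which is why calibration checks of the class mean use a 2 px eroded interior |
| `lesion_radius_range` | (0.16, 0.32)·min(H, W) | lesion fractions of roughly 8–32% |

Everything derives from `PhantomParams.seed` (one spawned stream per cube),
so datasets are bit-reproducible.

**What the phantoms do not model:** spatial texture inside lesions,
inter-patient skin-tone variation, specular highlights, wavelength-correlated
noise, or any radiative-transfer physics. Passing tests therefore
demonstrate that the machinery — architectures, training loop, metrics,
protocol — behaves correctly on data with known structure; they do not
establish clinical image quality.

## Architectures

**Generator.** The latent vector (dim 100, DCGAN convention) with the
smoothed label appended is treated as a 1 × 1 image and expanded by a
4 × 4 transposed convolution (a dense projection in conv form) to 4 × 4;
stride-2 stages (kernel 4, pad 1) double the spatial size until it covers
the requested output, remaining stages are stride-1 (kernel 3, pad 1);
the seventh stage maps to the output channel count. Stages 1–6 carry batch
norm + ReLU, stage 7 tanh. Because 50 is unreachable by stride-2 doubling
from 4, the map grows to 64 and is center-cropped; the crop keeps the
fixed 7-stage structure for any output size in [5, 128]. Channel widths
halve at each doubling from `base_channels` (512 at paper scale; tests use
32–64). The output has bands + 1 channels: the last is the mask channel,
binarized at the tanh midpoint 0 when converted back to a cube.

**Discriminator.** Six convolutions: stride 2 while the spatial size
exceeds 4, then stride 1; the last stage is a full-frame kernel producing a
single sigmoid probability. Stage 1 has leaky ReLU (slope 0.2) only,
stages 2–5 batch norm + leaky ReLU. In conditional mode the label is
broadcast as an extra input plane.

**Conditioning.** The documented injection is concatenation of the smoothed
scalar to z (input length latent_dim + 1). `GeneratorSpec.condition_channels`
optionally replicates the scalar over k input channels (default 1). At
desk scale the single-channel pathway is too weak to become
label-sensitive within short runs — batch norm attenuates the shift it
induces — so the scaled-down experiments use k = 16; the replication
changes only the input layer's width, not the injection semantics.

**Equalized learning rate.** When enabled, each layer's weights are
multiplied at every forward pass by `gain · √(2/fan_in)` (fan_in = input
channels × kernel area). The scaling is a pure reparameterization — scaling
raw weights by k while dividing the layer gain by k leaves the function
unchanged — whose purpose is to equalize effective per-layer learning
rates. Raw weights are initialized so the *effective* initialization is
N(0, 0.02) regardless of equalization: with unit-scale raw weights,
Adam's per-parameter normalization would shrink effective updates by
√(2/fan_in) and measurably stall short runs.

## Training

Binary cross-entropy losses; the generator uses the non-saturating form.
One step = one discriminator update on real + fake batches (targets
smoothed into [0.7, 1] / [0, 0.3] and role-flipped independently with
probability 0.05), then one generator update on a fresh batch. Adam with
betas (0.5, 0.999); L2 penalty 1e−5 on weights (not biases or batch-norm
parameters).

- **RGB pretraining**: 100 epochs, batch 128, lr 2e−4 for both networks,
  3-channel specs.
- **Transfer**: interior layers are copied verbatim; in the generator's
  output layer the parameter slices producing the three bands nearest
  630/532/465 nm receive the RGB model's R/G/B slices, and the
  discriminator's input layer likewise; all other new-channel parameters
  keep a fresh seeded initialization. A conditional upgrade adds input
  channels to the generator's first stage; the overlapping latent slice is
  copied.
- **HS conditional phase**: 200 epochs, batch 2, two time-scale updates
  with lr_G = 1e−4 < lr_D = 4e−4 (the convention that the discriminator
  runs on the faster time scale), equalized learning rate on. Smoothed
  targets are re-drawn every epoch so the discriminator cannot memorize
  fixed values; data order is reshuffled per epoch from a seeded stream.
- **Matching-aware discriminator** (default on, conditional mode): the
  discriminator additionally scores real cubes paired with the *opposite*
  class's label range as fakes. Without this term the discriminator can
  win on realism alone, never consults the label, and the generator
  receives no class-conditional gradient — verified directly at desk scale.
- **Mask channel**: judged adversarially along with the bands by default;
  an optional per-pixel BCE term against the real masks
  (`mask_aux_coeff`) is available but off by default.

A NaN in either loss raises a training-divergence error carrying the step
index. All stochastic components (latent draws, smoothing, swapping,
ordering, initialization) derive from the config seed through named
streams, so runs are exactly repeatable; named-stream splitting means
adding a stage never perturbs earlier streams.

## Evaluation

**FID.** ‖μ₁−μ₂‖² + Tr(Σ₁+Σ₂−2(Σ₁Σ₂)^{1/2}) between Gaussian fits to
feature embeddings. The matrix square root is computed by symmetric
eigendecomposition of Σ₁^{1/2} Σ₂ Σ₁^{1/2}; eigenvalues below a relative
−1e−8 tolerance are an error (reporting the minimum eigenvalue), small
negatives are clipped to zero. The canonical Inception embedding does not
exist for 116-band cubes and no pretrained weights ship with the package,
so the default embedding is a deterministic, bit-reproducible statistics
vector: per-band spatial mean, per-band spatial sd, and per-band
lesion/background contrast (3B features; contrast is zero without a mask).
A CNN embedding (pooled penultimate activations of the fidelity
classifier) is optional. Consequence, stated prominently: **absolute FID
values from this package are not comparable to Inception-based FIDs**;
only same-embedding comparisons (e.g. trained vs untrained generator) are
meaningful.

**Jensen–Shannon divergence.** Base-2 logarithms, so the value lies in
[0, 1]; 0·log 0 := 0. Spectral signatures are reflectances, not
distributions, so they are L1-normalized before comparison — the
divergence then compares signature *shape*, not amplitude.

**Confusion metrics.** Accuracy, precision, recall and F1 as percents
rounded to two decimals; a vanishing denominator yields None plus an
`undefined` flag rather than an exception.

**Fidelity protocol.** A compact residual network — stem convolution, four
residual blocks (two downsampling), global average pooling, sigmoid head —
is trained from scratch with Adam (default 50 epochs, lr 1e−3, width 16)
on the synthetic set only; training stops early once training accuracy
reaches 100%, the protocol's intended overfitting regime. The real set
enters only at scoring time (the trainer's interface receives only the
synthetic set). An ImageNet-pretrained classifier is deliberately not
used: the protocol must run without downloaded weights, and a from-scratch
network makes the "knowledge came only from synthetic data" claim exact.
With small training sets, use smaller batches so the batch-norm running
statistics see enough updates (the default momentum 0.9 needs a few dozen
steps to converge).

## Numerical and design notes

- Cube ↔ tanh-range conversion is affine [0,1] ↔ [−1,1]; the generated
  mask channel binarizes at 0.
- The discriminator's sigmoid input is clamped to ±30 so outputs are
  strictly inside (0, 1) in double precision.
- BCE probabilities are clipped at 1e−7 for loss gradients.
- Checkpoints are single-file archives: a version magic string, the
  generator/discriminator specs as JSON, and flat named parameter arrays.
- ENVI I/O writes one text header + band-sequential float32 raw file per
  cube (mask stored as a flagged trailing band); HDF5 holds one dataset per
  file under `/cubes/<id>/{data,mask}` with label and wavelength
  attributes. Round trips are bit-exact for HDF5 and float32-exact for ENVI.
- Exit codes of the CLI: 0 success, 2 configuration error, 3 data error,
  4 numerical/training divergence.

## Scaled-down experiment sizes

Desk-scale runs used throughout the test suite are chosen as the smallest
sizes at which each claim is still meaningful: 16 × 16 × 16 phantoms with a
76-cube cohort and 30 epochs for adversarial-training progress (FID vs the
untrained generator, conditioning sign test over 10 shared-latent pairs),
24 × 24 × 16 with 1000 cubes for the classifier-overfitting protocol, and
8–16 px geometries for unit contracts.

## Known limitations

- Adversarial training at batch size 2 is noisy; desk-scale runs learn
  global spectral statistics well before class-conditional differences, so
  short-run conditional structure is weak (the worked example's fidelity
  transfer illustrates this honestly).
- The deterministic embedding summarizes spectra, not spatial texture;
  a generator could in principle match it while producing implausible
  spatial patterns. The optional CNN embedding mitigates this.
- Fixed 7-stage/6-stage architectures cap the output size at 128 px.
- The phantom generator's simplifications listed above mean desk-scale
  results say nothing about real dermoscopic image quality.
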