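# Methods

This note records the model this package implements, the assumptions and
defaults behind it, what the synthetic phantoms do and do not establish, and
the numerical choices a maintainer would want to know. Everything quantitative
stated here is computed by the test suite or the acceptance script.

## Translation model

The generator is an encoder / residual-transformer / decoder network.

- **Encoder** (three convolutions): a 7×7 stem at `base_width` channels,
  then two stride-2 3×3 convolutions doubling the width each time, so a
  256×256 input becomes a `4·base_width`-channel 64×64 feature volume. With
  the paper-scale `base_width = 64` that is 256 feature channels at quarter
  resolution; the desk-scale training default is `base_width = 16`.
- **Transformer**: `n_res_blocks` residual blocks (reflection-padded 3×3
  convolutions, instance norm, identity skip). Default 9 at paper scale,
  2 in the desk-scale training config.
- **Decoder**: two upsampling stages followed by a 7×7 projection and a
  tanh, mapped affinely onto [0, L]. Each upsampling stage is
  nearest-neighbour ×2 followed by a 3×3 convolution (resize-convolution)
  rather than a strided transposed convolution: same upsampling role,
  simpler exactly-tested backward pass, and no checkerboard artifacts. The
  output nonlinearity being bounded is our choice; nothing constrains it
  externally.
- **Normalisation**: instance norm everywhere, in generator and
  discriminator. Batch statistics would mix information across samples,
  which hurts style transfer where per-image, per-pixel content matters.
- Inputs with spatial dims not divisible by 4 are reflection-padded and the
  output cropped back, so translation always preserves H×W.

Inputs are scaled to [−1, 1]. Label-free images are preprocessed by
intensity inversion I → |L − I| (dark-field background → bright-field
background, matching histology) and rendered into three colour channels
(2PA→red, SHG→green, 3PA→blue; SRS protein→green, lipid→blue, red zero).
The 3-channel representation lets one encoder ingest both domains, which the
identity-pass contrastive loss requires.

## Losses

**Adversarial.** A patch discriminator (4×4 convolutions, `n_layers`
stride-2 stages, instance norm, leaky ReLU) outputs a grid of logits; the
objective is the logarithmic GAN form, E[log D(y)] + E[log(1 − D(G(x)))],
with the non-saturating generator objective −E[log D(G(x))]. A
least-squares variant is available behind `gan_variant="least_squares"` for
experimentation; the logarithmic form is the default because it is the form
the total objective is defined with. All sigmoid/log terms go through
softplus-based stable primitives.

**PatchNCE.** For each chosen encoder layer l (default: the raw input, the
three encoder convolutions, and the first residual block), 256 random
spatial locations are sampled — the *same* locations in the input and
translated feature stacks — projected by a per-layer two-layer MLP to K
dimensions and L2-normalised. Unit-sphere normalisation prevents the
encoder from trading similarity for magnitude (feature expansion/collapse).
Each translated-image query is classified (N+1)-ways against its positive
and the N = 255 other sampled locations at temperature τ = 0.07; too large
a τ flattens the logits (no learning signal), too small a τ over-weights
the hardest negatives, which in practice can be latent positives.

The identity-pass loss feeds the target-domain image y through the
generator and mirrors the construction with roles swapped: queries are
features of y, keys are features of G(y). (The better-known reference
implementation of contrastive unpaired translation orients the identity
loss the other way, with queries from G(y); the two differ by a
row-vs-column softmax and are numerically close. We follow the printed
definition.)

**Reduction convention.** The printed loss sums the cross-entropy over
layers and sampled locations. Summation makes the contrastive terms ~10³
times the adversarial term, and with all loss weights fixed at 1 the
adversarial gradient is then negligible: in a controlled phantom run (2000
iterations, fixed seed) the generator's pixel error against ground truth
*rose* under the summed loss and fell by a factor of 8 under the averaged
loss. Training therefore defaults to the per-location **mean**
(`nce_reduction="mean"`), which puts the contrastive terms on the
adversarial loss's scale so that λ = λ_X = λ_Y = 1 is meaningful; the
functional loss API defaults to the printed sum. The two differ by the
constant factor (number of locations) per layer.

**Cross-contrastive mode.** A momentum copy of the encoder+projectors
(θ_aux ← m·θ_aux + (1−m)·θ_main, m = 0.999 default) encodes each training
image; its projected features are pushed into per-layer FIFO queues
(capacity 1024 default). Queries take these external vectors as extra
negatives. On the first iterations the bank is empty and the loss reduces
exactly to the self-contrastive one (warm-up). The bank holds X-domain
momentum features by default; which domain should feed it is genuinely
open, so it is a documented choice rather than a claim. m and the capacity
are unconstrained externally; the defaults follow common momentum-encoder
practice.

## Training

Adam with learning rate 2·10⁻⁴ and β₁ = 0.5, β₂ = 0.999, batch size 1 (the
instance-norm regime), alternating discriminator and generator+projector
steps on randomly cropped tiles with flip/90°-rotation augmentation. The
learning rate is constant for the first half of training and decays
linearly to ~0 over the second half (only the initial rate is externally
fixed). Paired mode presents corresponding (x, y) crops in the same step;
unpaired mode samples the two domains independently. Test/train splits are
disjoint at a configurable test:train ratio (test share = round(n·t/(t+r)),
minimum 1); validation patches are drawn from the train partition only, and
the run record carries the partition for audit.

Checkpoints are snapshotted at the validation cadence. "Best qualitative
validation performance" is not automatable, so selection is quantitative:
lowest validation pixel error against the paired target when pairs exist
(phantoms), otherwise lowest validation PatchNCE(X); both scores are
recorded for every snapshot.

Training runs in float32 by default for throughput (`dtype` in
`TrainConfig`); all oracle-facing computation and the default tensor dtype
stay float64. The whole stack is single-process and deterministic given the
seed: two runs with the same config produce bitwise-identical loss logs.

## Stain deconvolution and morphometry

Optical density is OD = −log₁₀(max(I, ε)/L) per RGB channel with ε = 1
intensity unit; the floor (rather than an additive offset) keeps the
transform an exact inverse of the forward model for I ≥ ε while still
guarding log(0). Concentrations are OD projected through the inverse stain
matrix, clamped at 0. The default stain matrix is the published
Ruifrok–Johnston H&E pair with the residual completed as their normalised
cross product; it is overridable per dataset. Component intensity is the
mean of the colour-inverted rendered single-stain image,
I_stain = mean(|L − I_deconv|) over the whole tile (a tissue mask is a
documented alternative; whole-tile is the default since nothing fixes the
masking). An essentially white image has no defined hematoxylin proportion
and returns a flagged null.

Nuclear segmentation (classical fallback): hematoxylin concentration →
Gaussian smoothing (0.5 µm) → Otsu threshold → hole filling and small-object
removal → distance-transform watershed to split touching nuclei → area
filter (8–400 µm²). Star-convex deep detectors plug in as any callable
returning the same records; the fallback is the tested default. Centroids
and areas are in micrometres, so a pixel size is mandatory.

Nearest-neighbour distances are Euclidean distances between nuclear
centroids (KD-tree; exact against the O(n²) all-pairs oracle). Confidence
intervals are normal-approximation mean ± 1.96·SE — the simplest procedure
consistent with a stated 95% level; coverage is verified empirically at
95% ± 2% over 1000 simulations. Distribution comparisons use the two-sample
KS test with the conventional banding (ns > 0.05 > * > 0.01 > ** > 0.001 >
*** > 0.0001 > ****). Histograms default to Freedman–Diaconis bins with a
fixed-edge override for cross-image comparability.

## Grid classification

Images are partitioned into 334 µm × 334 µm cells (the physical cell size
is the externally fixed quantity); each cell is classified independently by
a plugin callable returning a probability vector over {normal, IA, IC, IIC,
IIIC}, renormalised defensively. Edge cells with under 50% of the nominal
area are skipped and flagged. The accuracy map is the per-cell delta
function (argmax class vs truth); argmax ties — measure-zero in practice —
resolve to the lowest class index with a warning counter. The bundled
reference CNN (3 stride-2 convolutions → global average pool → linear head,
He-scaled init) is a desk-scale stand-in that honours the plugin contract,
not a clinical model.

## Synthetic phantoms — what they are and are not

A phantom is rendered from explicit geometry: elliptical nuclei (log-normal
areas, uniform orientation, axis ratio 0.65–1) placed by a hard-core point
process; collagen-like fibers as smoothed oriented segments (von Mises
orientation, κ = 2); smooth cytoplasmic texture (8 µm correlation length).
Channels: 2PA-like = cytoplasm with dark nuclei (high SNR), SHG-like =
fibers, 3PA-like = blurred diffuse signal with Poisson–Gaussian noise
(lowest SNR of the three, by construction and by measurement). The pseudo-
H&E is rendered from the *same* geometry through the package's own stain
forward model (hematoxylin ∝ nuclei, eosin ∝ cytoplasm + fibers, OD → RGB),
so deconvolution and morphometry have exact ground truth. Optional
misregistration (rigid offset, default 3 µm, + elastic jitter, default
1.5 µm, when enabled) emulates adjacent unregistered sections and is ON for
training datasets, OFF for oracle fixtures.

Stage presets step density 450 → 1000 nuclei/mm² and median area 30 → 40 µm²
monotonically from normal to stage IIIC, tracking the qualitative link
between stage, nuclear density and pleomorphism; at the IIIC preset the
mean nearest-neighbour spacing (~16 µm) and nuclear areas (~40 µm²) sit in
the range reported for real ovarian tissue at this magnification. The
densities are far below confluent real tissue, which keeps hard-core
placement trivially feasible and nuclei well separated.

Hence a green test establishes that the machinery is self-consistent — the
losses match their closed forms, the forward and inverse stain models agree,
segmentation recovers planted geometry, training reduces pixel error on
in-distribution phantoms. It does **not** establish clinical image quality,
generalisation to real SRS/multiphoton tissue, or the published tissue-level
numbers (hematoxylin proportions of real H&E, staging accuracy of trained
clinical classifiers), which require the original datasets and model zoo.

## Numerical choices

- All autodiff primitives are verified against central finite differences.
- Softmax-type quantities (NCE, log-sum-exp, GAN logs) are computed with
  max-subtraction / softplus; the NCE loss is finite for any unit-norm
  inputs.
- Tile stitching uses separable linear feather weights (distance to tile
  border), normalised to sum to 1 at every pixel; any blend is a convex
  combination of contributors and single-contributor pixels are copied
  verbatim. The blend profile is our choice; only "blending with 50%
  overlap" is externally fixed.
- Crosstalk correction I_SHG − I_2PA clamps at 0: negative intensities are
  unphysical.
- Tiling re-anchors the last row/column tile to the image border instead of
  padding, so every tile contains only real pixels.
- Quantisation to the original bit depth happens only at write time; all
  processing is floating point.
- Default pixel size when metadata is absent: 634/1024 µm ≈ 0.62 µm (a
  634 µm field of view sampled at 1024 px).

## Known limitations

- Pure-NumPy training is ~2 orders of magnitude slower than a GPU framework;
  the package targets desk-scale experiments (tiles ≤ ~128 px, thousands of
  iterations), not full-resolution clinical training.
- Batch size is effectively 1; there is no distributed or mixed-precision
  path.
- The classical nucleus segmenter under-performs star-convex deep detectors
  on crowded, textured real tissue; it is calibrated for the phantom regime
  (well-separated nuclei, clean hematoxylin contrast).
- The phantom generator does not model out-of-focus light, vignetting,
  stitching seams, staining variability, or nuclear chromatin texture.
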