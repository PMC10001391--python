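# Methods

## Scope and design

`brainseg` implements a 2D multi-encoder attention U-Net for BraTS-style
brain-tumor segmentation: preprocessing from 3D NIfTI volumes to normalised
slices, the network itself, dice-loss training, and region-wise evaluation.
The package targets slice-level (2D) segmentation; whole-volume 2.5D/3D
processing, bias-field correction, registration and skull stripping are out
of scope (BraTS inputs arrive co-registered, resampled to 1 mm³ and
skull-stripped).

Because the package is built directly on NumPy, it ships its own
reverse-mode autodiff core (`brainseg.nn`): NHWC tensors, im2col-based
convolutions (full and depthwise), max pooling, nearest/bilinear ×2
resampling, batch normalisation, softmax, Adam and SGD. Every operation's
analytic gradient is tested against central finite differences in float64;
production arrays are float32. The engine is intentionally minimal — no
graph optimisation, no accelerator support — and is sized so the full
224×224 three-encoder network (≈47 M parameters) runs a forward pass in
seconds on one CPU core.

## Preprocessing

- **Slice choice.** One axial plane per case: index 90 for the canonical
  155-slice depth (the plane where all compartments are typically visible),
  otherwise `floor(D/2)`. The slice is treated as the "middle" plane, so the
  generalisation to other depths is the literal middle.
- **Crop.** Centre crop to 224×224 (from 240×240 this removes an 8-pixel
  background margin on each side). For odd margins the trailing side
  receives the extra pixel — an arbitrary but fixed tie-break.
- **Denoising.** Gaussian blur, default σ = 0.5 px (configurable; σ = 0
  disables). Applied after cropping and before normalisation.
- **Normalisation.** Per-channel z-score with the *population* standard
  deviation, the image-processing convention. Constant images are rejected
  rather than silently emitting NaN.
- **Channel order.** The network input stacks [t1, t1ce, t2]; flair is read
  and carried by the loaders but not fed to the network (three channels are
  required by the ImageNet-style encoder stems). Modality-tagged arrays are
  validated so a mis-ordered call fails loudly.
- **Labels.** BraTS file code 4 (enhancing) is remapped to internal class 3
  so the 4-way softmax indexes densely {0,1,2,3}; writers map back to file
  codes.
- **Augmentation.** Horizontal/vertical flips, rotations in multiples of
  90°, additive Gaussian noise on the image only (std 0.05 of the
  normalised range), and integer translation up to 10 px with zero padding.
  All label transforms are pixel permutations or zero fills, so labels are
  never interpolated. Magnitudes are package choices; deterministic under a
  seed. Augmentation is offline (a materialised list), which keeps training
  fully reproducible.

## Encoders and tap points

VGG-19, ResNet50 and MobileNetV2 are built to their standard schedules with
classification heads removed and all layers trainable (fine-tuning).
Nothing names the internal layers that feed the pyramid, so the taps are
chosen to satisfy the published shape contract:

- **VGG-19** — last activation of each of the five conv blocks, pre-pool:
  natively (224, 112, 56, 28, 14).
- **ResNet50 / MobileNetV2** — the five distinct-resolution stage outputs;
  their stride-2 stems put these at (112, 56, 28, 14, 7), and the lateral
  projection (1×1 conv to 32 channels) resizes each level one octave up
  onto the canonical grid.

ResNet's stem pool is a 2×2/stride-2 max pool (the engine's pooling
primitive) rather than 3×3/stride-2; resolutions and the shape contract are
unaffected. ImageNet-pretrained initialisation is an opt-in hook
(`pretrained` flag + `load_state` from a local weights file); default
initialisation is He-normal so construction is always offline. A width
multiplier scales all stages; the "tiny" profile (input 64, pyramid 8
channels, width 1/8) exercises the identical topology at desk scale.

## Bidirectional pyramid

One bidirectional pass (top-down to `L1out`, bottom-up to `L5out`) with
*unweighted* sums exactly as the eight assignments are written — the
EfficientDet fast-normalised fusion weights are deliberately not used. The
"Conv" of each node is interpreted as the depthwise-separable fusion block
(3×3 depthwise + 1×1 pointwise, BN + ReLU after each convolution); the
32-kernel 1×1 convolution is used for lateral projection. This
disambiguation is flagged as an interpretation, not asserted as the source
design. Resize is bilinear ×2 upsampling and 2×2 max-pool downsampling,
both stride 2; the interpolation kernel is a package choice. The finest
level has no mid node — the top-down chain emits `L1out` directly. The pass
count is a config knob defaulting to 1. The layer is written over
injectable conv/resize callables so tests can replace them with stubs and
compare against a straight-line oracle sharing no code.

## Fusion, attention decoder, head

Per level the three 32-channel maps are concatenated (96) and projected
back to 32 with a 1×1 convolution; a learnable merge subsumes summation,
and an element-wise-mean mode is kept as a config alternative. The coarsest
fused level (14×14×32) is the decoder bottleneck.

Each UpAtt stage: the gating signal is the coarser decoder feature through
a 1×1 conv + BN, bilinearly upsampled to the skip's resolution (recomputed
at every depth); the additive attention gate uses 1×1 channel-wise maps
Wx (no bias), Wg (+b_g) into a 128-channel intermediate, ReLU, then ψ
(+b_ψ) to a single channel and a sigmoid, giving α ∈ [0,1] broadcast over
the skip's channels. Gate parameters are Xavier-initialised; other layers
use He. The gated skip is concatenated with the ×2-upsampled decoder
feature and passed through a double 3×3 convolution (128 channels, BN +
ReLU each). Four stages return to input resolution; the head is a 1×1
convolution to 4 channels, BN, per-pixel softmax.

Ablation variants are constructible by name: each single encoder or all
three, with or without the bidirectional pyramid, with the attention or the
plain decoder (raw-skip concatenation); `3encoder+bifpn+attdecoder` is the
default.

## Training protocol

Soft dice per class over all batch pixels with the squared-denominator
form, smoothing ε = 10⁻⁶ in numerator and denominator (guards empty
classes); loss = 1 − unweighted mean over the four classes. Adam at
framework-default betas; the schedule α₀(1−e/Nₑ)^0.9 is stepped per epoch
(e is an epoch counter). Defaults α₀ = 10⁻⁴, Nₑ = 350, batch 5 mirror the
full-scale protocol; desk-scale runs use fewer epochs and a larger rate.
The 80:10:10 split takes floor(0.8·n) for training and halves the remainder
(369 → 295/37/37), deterministically under a seed. The checkpoint criterion
is validation dice (chosen over validation loss; the two coincide up to
sign for this loss). Training is single-process and deterministic for a
fixed seed.

## Evaluation

Regions from internal classes: WT = {1,2,3}, TC = {1,3}, EnT = {3} (file
coding {1,2,4} supported symmetrically). Metrics per region: DSC, IoU, HD95
and confusion-table accuracy/precision/recall/F1.

- The IoU is the standard `|∩|/|∪|` — consistent with the identity
  IoU = DSC/(2−DSC) that the reported whole-tumor operating point
  (DSC 0.8741 ↔ IoU 0.7764) satisfies exactly.
- HD95 takes the 95th percentile of boundary nearest-neighbour distances in
  each direction and reports the maximum — the community meaning of the
  "95"; the sup-inf (100th percentile) reading is available via the
  `percentile` argument and covered by the oracle tests.
- Boundaries are mask pixels with a 4-connected background neighbour, with
  a full-mask fallback for single-pixel masks. Distances scale with the
  voxel spacing (mm).
- Degenerate conventions: both masks empty → DSC = IoU = 1 and HD95 = 0;
  exactly one empty → HD95 is NaN and excluded from split averages; zero
  confusion-table denominators → 0 with a `degenerate` flag.
- Split summaries are per-case means (not pooled-voxel metrics); pooling
  would generally break the per-pair DSC↔IoU identity in the aggregate.

## Synthetic phantoms

A phantom is an elliptical "brain" containing three nested tumor
ellipsoids: edema shell (file code 2), enhancing rim (4), necrotic centre
(1), so EnT ⊆ TC ⊆ WT by construction and all three regions are non-empty
on the default slice. Modality contrasts make t1ce brightest in the rim and
flair brightest in edema — the qualitative clinical ordering — with
additive Gaussian noise (std 0.05). Default test shape is 64×64×32 for
speed; 240×240×155 is available for integration runs. Dataset generation
jitters tumor size (±15%) and position (±5% of width) per case.

What the phantoms do *not* model: MRI physics (bias fields, partial
volume, acquisition noise statistics), anatomical texture, multi-focal or
irregular tumors, inter-rater label noise. Passing tests therefore
demonstrate mechanical correctness of the pipeline and learnability of a
clean, well-separated contrast structure — not clinical-grade accuracy on
real BraTS volumes; published benchmark numbers require the real dataset
and GPU-scale training and are intentionally not claimed.

## Numerical choices and problem sizes

Float32 throughout the network; float64 in preprocessing and metrics.
Sigmoid inputs are clipped to ±88 (the float32 exp range) — exact in
saturation. Max-pool gradients route to the first maximal element.
BatchNorm uses momentum 0.1 and ε = 10⁻⁵, with batch statistics in
training and running statistics in inference. The test suite exercises the
full-width 224 network only for shape/finiteness conformance (one forward
pass); all learning checks use the tiny profile, where 50 Adam steps at
rate 2×10⁻² overfit four phantom slices to a training dice above 0.9 in
about half a minute on one CPU core.

## Known limitations

- 2D only; the slice-level view discards through-plane context.
- The NumPy engine is CPU-bound; full-scale *training* at 224×224 is not
  practical here (a single forward+backward is, and is tested).
- Pretrained encoder weights are plumbing only — no converter from
  framework checkpoint formats is included, so transfer learning requires
  a locally prepared `state` file.
- Offline augmentation multiplies memory, not epochs; acceptable at the
  slice counts this package targets.
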