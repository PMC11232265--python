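# Methods

## The fusion model

`res2fuse` fuses a registered pair of single-channel images — a CT slice
`I_ct` and an MR slice `I_mr` of the same anatomy — into one image `I_f`
that keeps the CT's high-contrast bone signal and the MR's soft-tissue
detail. The model has three parts:

**Feature extractor.** Two 3×3 convolutions (1→32, 32→64, both ReLU)
followed by a scale-4 Res2Net block. The block squeezes through a 1×1
convolution (64→64, ReLU), splits the result channel-wise into four
ordered groups x₁…x₄ of 16 channels, and chains them through 3×3
convolutions Hᵢ with inter-group residual additions:

    y₁ = x₁
    y₂ = H₂(x₂)
    yᵢ = Hᵢ(xᵢ + yᵢ₋₁),  i ∈ {3, 4}

The yᵢ are concatenated back to 64 channels and passed through a closing
1×1 convolution (64→64, ReLU). Because group i sees the accumulated output
of groups 2…i−1, the four groups carry effective receptive fields of
increasing size — multiscale features from a single layer. All
convolutions are stride 1 with zero padding, so spatial size is preserved
end to end (the per-position fusion weights require it).

**Fusion layer (inference only, no parameters).** For each source i the
channel-wise mean Qᵢ(x, y) of its 64-channel feature stack is taken at
every position, and per-pixel weights are the L1 normalization

    ωᵢ(x, y) = Qᵢ(x, y) / (Σⱼ Qⱼ(x, y) + ε),   ε = 1e-8,

with a uniform 1/s fallback at pixels where every source is exactly zero.
Fused features are the convex combination f(c, x, y) = Σᵢ ωᵢ(x, y)
φᵢ(c, x, y), the same weight broadcast over all channels. Features arrive
post-ReLU, so the weights are well defined; negative inputs trigger a
contract warning and are clamped. Two alternative readings are preserved
as options: `weight_mode="softmax"` (exponentiated means) and
`local_window=k` (box-filtered means), both off by default because the
plain normalized mean is the precise rule the weight equation states.
`addition` and `average` baselines are registered for comparison runs.

**Reconstructor.** Four 3×3 convolutions 64→64→32→16→1; the first three
carry ReLU, the last is linear. At inference the output is clamped to
[0, 1]. During training the loss sees the *pre-clamp* linear output — a
hard clamp inside the training graph would zero the gradient at saturated
pixels and stall early learning; the clamp is purely an output-range
guarantee.

## Training protocol

Training is a single-image reconstruction task: the fusion layer is never
instantiated (the test suite asserts this structurally). Each batch runs
image → extractor → reconstructor and minimizes the hybrid loss

    L = L_ssim + L_pixel
    L_ssim  = 1 − SSIM(I_out, I_in)
    L_pixel = ‖I_out − I_in‖² / (B·C·H·W)

with unit term weights. SSIM uses the de-facto standard windowed form:
11×11 Gaussian window, σ = 1.5, c₁ = (0.01 L)², c₂ = (0.03 L)², dynamic
range L = 1 on normalized intensities, averaged over fully supported
window positions. Since the network is pure NumPy, the gradient of the
SSIM term is implemented in closed form by differentiating through the
three filtered moments G∗x, G∗x² and G∗(xy) and applying the adjoint
(full-mode) window filter; it is verified against finite differences.

The optimizer is Adam (β₁ = 0.9, β₂ = 0.999) at the published learning
rate 1e-4 with batch size 4. Weight initialization is fan-in-scaled
uniform, U(−1/√fan_in, +1/√fan_in), fully seeded. Each epoch draws one
fresh random crop per pool image and shuffles; crop offsets, shuffling and
initialization all derive from one seed, so a run is bit-reproducible.

Defaults at desk scale: 30 epochs on 64 phantom crops of 64×64 (the
published configuration trains on 10,000 clinical 256×256 crops; the
desk-scale sizes keep a full three-seed training study inside a few
minutes on one CPU while leaving the protocol itself unchanged).

## Quality metrics

Eight standard fusion indices compare a fused image F against its sources
A, B (conventions recorded in the report):

- **AG** — mean over the (M−1)(N−1) grid of √((ΔᵥF² + ΔₕF²)/2); computed
  on the [0, 1] intensity scale.
- **SF** — √(RF² + CF²) with RF, CF the row/column first-difference
  energies normalized by MN. The textbook definition indexes a
  non-existent zeroth neighbor at the border; the sums here run over valid
  index pairs while keeping the printed 1/(MN) normalization.
- **EN** — Shannon entropy (bits) of the histogram after quantization to
  `levels` gray levels (default 256). Note the histogram-MI/EN estimators
  are biased upward by ≈ (K−1)²/(2N ln 2) for K bins on N pixels.
- **MI** — default `fusion_standard` mode: MI(A; F) + MI(B; F) from 2-D
  joint histograms, i.e. the information the fused image retains from each
  source; `pair_literal` mode gives MI(A; B) between the sources only.
- **PSNR** — 10 log₁₀(r²/MSE) with MSE the mean of the two source-vs-fused
  MSEs; the peak r defaults to the fused image's own maximum
  (`peak="fused_max"`), with the conventional full-scale r = 1 available.
- **SSIM** — mean of windowed SSIM(A, F) and SSIM(B, F), same window as
  the loss; the standard two-term closed form (the three-component form
  with c₃ = c₂/2 collapses into it).
- **Qabf** — Xydeas–Petrović edge preservation: Sobel strength and folded
  orientation per image; per-pixel preservation factors from relative
  strength and orientation agreement through the standard sigmoids
  (Γ_g = 0.9994, κ_g = −15, σ_g = 0.5; Γ_α = 0.9879, κ_α = −22,
  σ_α = 0.8), combined weighted by source edge strengths.
- **VIFF** — four-scale pixel-domain visual-information fidelity: at each
  Gaussian-pyramid scale, Gaussian-windowed local statistics give the GSM
  information terms for each source-vs-fused pair; at every position the
  source with the larger reference-information term is selected, and
  per-scale fidelity ratios are combined with fixed decreasing weights
  (0.5, 0.25, 0.15, 0.10, normalized). Computed on the 0–255 scale, on
  which the model's noise variance σₙ² = 2 is defined. Equals 1 when
  F = A = B.

A paired two-sided t-test utility compares per-image metric columns
between two methods. Zero-variance differences are degenerate; the
utility then reports p = 0 for a nonzero mean difference and (t, p) =
(0, 1) for identical columns, with a warning.

## Synthetic phantom generator

Clinical MR/CT pairs are not shippable, so the generator draws seeded
head-slice phantoms: a rotated head ellipse with a closed skull ring
(thickness 2–6 px), inner soft tissue, a small ventricle, and 0–2
circular tumors (radius 5–15 % of the image) kept strictly inside soft
tissue by a 2 px guard band. Both modalities render from the *same* label
map, so every pair is registered by construction. Intensity assignments
reproduce the modality contrast the fusion method exploits — CT: skull
0.95, soft tissue 0.35, tumor 0.38 (lesions nearly invisible), ventricle
0.25; MR: skull 0.05, soft tissue 0.55 plus a Gaussian random texture
field (amplitude 0.15, correlation length 1.5 px — short, for the fine
tissue texture characteristic of T1 MR), tumor 0.85 with a sharp boundary,
ventricle 0.20. A mild partial-volume blur (Gaussian σ = 0.4) and additive
Gaussian sensor noise (default σ = 0.01) finish the render.

What the phantom does *not* emulate: Hounsfield calibration, Rician MR
noise, k-space artifacts, 3-D geometry, a scalp/fat layer, and real
anatomical texture statistics. One consequence is measurable: in real
head imaging MR is the detail-rich modality, while in the phantom the CT
skull ring (a 0→0.95 step) dominates the total gradient budget and the MR
render carries about half the CT's average gradient. A convex per-pixel
fusion can therefore raise entropy over the CT source (it does,
consistently) but not its average gradient — the fused AG lands between
the two sources' at ≈ 0.8 of the CT's. Passing tests on the phantom show
the pipeline's mechanics and the attention strategy's edge-preservation
advantage; they do not certify metric gains on clinical data.

## Numerical choices

- Network arithmetic in float32 (GEMM-based im2col convolutions); losses
  and metrics in float64.
- Convolution gradients avoid a scatter pass: the input gradient is the
  transposed convolution with flipped kernels, the weight gradient a
  batched GEMM against the cached im2col matrix.
- ε = 1e-8 in the fusion weights guards all-zero denominators; exactly
  zero pixels fall back to uniform weights.
- Histogram quantization is round-to-nearest onto levels−1 steps.
- Image write quantization rounds half away from zero (0.5 → 128 at
  8 bit).
- `group_conv_depth=2` builds two stacked 3×3 convolutions per Res2Net
  group (an alternative reading of the layer table); the default is one,
  as the block's defining recurrence specifies one Hᵢ per group.

## Known limitations

- CPU-only and desk-scale; no GPU path, no 3-D volumes, no DICOM reader
  (NIfTI slices cover volumetric sources).
- No registration: inputs must be pre-aligned, and size mismatches are
  rejected rather than resampled.
- The SSIM loss term is only approximately invariant to a common intensity
  offset (the luminance term depends on it); exact invariance holds only
  for the contrast/structure factors.
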