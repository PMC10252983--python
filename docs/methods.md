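# Methods

`skintex` implements a unified pipeline for segmenting the two dominant
morphological skin features in facial photographs — wrinkles and enlarged
pores — with a single lightweight network, together with the semi-automatic
ground-truth scheme that makes training such a network affordable, the
classical image-processing detectors it is compared against, and a
synthetic data generator that stands in for clinical photographs.

## 1. Shape-prior texture-map ground truth

Manual annotation of wrinkles and pores is slow, and annotators deliberately
draw *over-thick* strokes so that the true feature is guaranteed to lie
inside the marking. The package converts such coarse annotations into
continuous training targets by multiplying them with a per-class *texture
map*: a filter response that is large exactly where the class's morphology
is present.

**Wrinkles.** With the grayscale image `I` normalized to [0, 1]
(luma weights 0.299/0.587/0.114),

    T_w(x, y) = (1 − I(x, y) / (1 + (I ∗ G_σ)(x, y))) · 255 .

A pixel darker than its Gaussian-blurred surround scores high; the blur
(default σ = 5 px, reflective borders) links collinear dark pixels into
coherent ridges. Keeping `I` in [0, 1] is essential: the denominator then
lies in [1, 2] and `T_w` spans the full 0–255 range, whereas raw 8-bit
values would compress every mid-tone toward 255. A cutoff (default 64 on
the 0–255 scale, configurable) is applied before multiplication with the
annotation.

**Pores.** Pores are pits a few pixels wide, so they are isolated with a
band-pass from a Burt–Adelson Laplacian pyramid built with the separable
5-tap binomial kernel (1, 4, 6, 4, 1)/16:

    t = −L0 + Expand(L1),      T_p = t · 1[|t| > Th],

then mapped affinely to 0–255 (`t ↦ 255 · clip(t, 0, 0.25)/0.25`; negative
`t` — bright specks — is discarded). The sign flip makes dark pits
positive. The default hard threshold is Th = 4/255 on the [0, 1] intensity
scale. Only pyramid levels 0–1 enter the formula, so a 3-level pyramid
suffices.

Two numerical points matter here:

* **Expand is implemented in polyphase form** — even-phase taps (1, 6, 1)/8
  with a reflective border, odd-phase neighbor averaging with edge
  replication when the target length is even. This is identical to the
  classic zero-insertion-then-doubled-blur construction in the interior but
  keeps the DC gain exactly 1 at the borders, so constant images have
  identically zero Laplacian levels and the pyramid reconstructs its input
  to machine precision.
* The band-pass `t` responds to pits of roughly 1–2 px Gaussian radius and
  *changes sign* for pits wider than ≈2 px — wide depressions are invisible
  to this ground-truth scheme by design. The synthetic generator therefore
  draws pores with σ ∈ [1.0, 1.6] px.

## 2. Network family

All models are U-shaped encoder–decoders whose blocks are the standard
double (3×3 conv → batch-norm → ReLU) unit, with 2×2 max-pooling between
encoder levels and bilinear upsampling followed by convolution in the
decoder (a 2×2 transposed-convolution variant is also available). Input is
a 3-channel color crop, output a 2-channel map — wrinkle and pore targets
regressed jointly in concatenated form by a final 1×1 convolution with *no*
output nonlinearity, since training minimizes MSE against continuous 0–255
ground truth.

Channel plan (depth *d*, base width *b*): encoder widths `b, 2b, …,
b·2^(d−2)` with a halved bottleneck `b·2^(d−2)`; decoder double-convs use a
halved mid-width. With d = 5, b = 64 this is the standard vanilla U-Net
variant with 17,263,042 trainable parameters (17.3 M); b = 32 gives the
*reduced* model (4,318,434 ≈ 4.3 M, a quarter of the vanilla count since
conv weights scale with the product of adjacent widths).

**Spatial attention (bottleneck only).** Channel-wise max and mean maps are
concatenated (2 channels), passed through one 7×7 convolution and a
sigmoid; the resulting per-pixel gate in (0, 1) multiplies the bottleneck
features. 99 parameters.

**Additive attention module (every skip connection).** Decoder features are
upsampled and processed by conv3×3 → BN → ReLU to form the query `q`;
encoder features serve as key and value. The gate is

    g = sigmoid( ψ( ReLU(W₁ k + W₂ q + b) ) )

with 1×1 projections: W₁ (key, no bias), W₂ (query, carries the bias), and
ψ reducing to a single channel before the sigmoid. Gated encoder features
are concatenated with `q` and passed to the decoder block. Internal gate
width is half the encoder width at each level. On the reduced plan these
two mechanisms add 871,943 parameters, giving 5,190,377 ≈ 5.2 M.

**Zero-padding positional bias.** The input is framed with `Z/2` rows and
columns of zeros per side (default Z = 32), producing a `(Z+H)×(Z+W)×3`
input and a same-size 2-channel output that is cropped back to `H×W` after
inference. The border zeros give the convolution stack an absolute spatial
anchor, letting it learn that wrinkles occupy the forehead/eye zones and
pores the butterfly (nose + cheeks) zone. Padding adds *zero* parameters:
the padded and unpadded attention models have bit-identical state
dictionaries at equal seeds.

The network stack is written on a small vectorized reverse-mode autodiff
engine over NumPy (im2col GEMM convolutions, closed-form batch-norm
backward, matrix-form bilinear upsampling). Every analytic gradient is
verified against central differences in the test suite, and each forward
primitive against an explicit-loop oracle.

## 3. Training and evaluation

Adam (β = 0.9/0.999), MSE loss between the 2-channel prediction and the
texture GT (GT zero-padded to the padded grid), with a global-norm
gradient-spike clip (200) as divergence insurance and an optional cosine
learning-rate decay. After the last epoch the batch-norm running statistics
are re-estimated by one forward-only pass over the training set with
cumulative momentum: at short budgets the exponential running averages lag
the rapidly moving weights, and without re-estimation eval-mode predictions
are mis-normalized relative to train-mode ones, which corrupts validation
losses for reasons unrelated to model quality. Weight init is He-normal,
seeded; one fixed sample permutation (derived from the seed) is reused
every epoch, which makes runs bit-reproducible and keeps the loss exactly
constant when the learning rate is zero. Continuous predictions are
binarized at 64 (wrinkle) and 32 (pore) on the 0–255 scale before IoU
`|X∩X̂| / |X∪X̂|`; aggregate IoU pools intersections and unions over the
evaluation set (per-image values are also reported), with IoU defined as 1
when both masks are empty and 0 when exactly one is.

## 4. Classical baselines

* **Wrinkles — Frangi vesselness.** Hessian per scale via scipy Gaussian
  derivative filters, normalized by σ²; with |λ₁| ≤ |λ₂|, the response is
  `exp(−R_B²/2β²)·(1 − exp(−S²/2c²))`, R_B = λ₁/λ₂, S = √(λ₁²+λ₂²),
  maximized over scales, with an *explicit* polarity gate (dark ridges
  require λ₂ > 0). The gate is implemented directly because formulations
  that rely on eigenvalue clipping fail to suppress ideal straight ridges
  of the wrong polarity, where the tangential eigenvalue is exactly zero.
  Defaults: scales {1, 2, 3} px, β = 0.5, c = 0.08 on [0, 1] images,
  binarization at 0.2.
* **Pores — high-pass + k-means + morphology.** Residual after Gaussian
  blur (σ = 3), k-means (k = 3, fixed seed, ≤100 iterations) on per-pixel
  residuals, darkest cluster kept, disk opening (radius 1), connected
  components outside [2, 200] px² removed. A uniform image degenerates
  (fewer distinct values than clusters) and yields an empty mask. The exact
  upstream pipeline this reconstructs is not published; these defaults are
  a reconstruction.

Both baselines accept a region-of-interest mask, mirroring how such methods
are evaluated on pre-cropped target areas.

## 5. Synthetic data generator

Each sample is a 96×96 (configurable) color crop emulating a face-derived
skin patch: low-pass-filtered Gaussian noise around a mean skin tone
(± a linear lighting ramp), dark spline strokes of per-stroke thickness
1.5–3.5 px and contrast 0.35 inside the wrinkle zone (top-30 % forehead
band plus two 15 %×15 % eye-corner boxes), 25 non-overlapping Gaussian pits
(σ 1.0–1.6 px, contrast 0.45) inside the central 40 %×60 % butterfly box,
and 10 *distractors* — pore-like pits and short strokes, visually matched
to the genuine features — strictly outside both zones. Fine truth masks
mark pixels where a feature's intensity drop exceeds half its contrast
(within 1.177σ of a Gaussian profile's center); coarse annotations are disk
dilations (default radius 3 px) of the fine masks. Distractors appear in no
annotation, so only positional information can tell them from genuine
features — the property the zero-padding mechanism is designed to exploit.

What the generator does *not* emulate: photometric color variation
(pigmentation, erythema), sebum highlights, hair, perspective distortion of
real faces, and annotation noise beyond uniform over-thickness. Passing the
synthetic study therefore demonstrates the mechanisms (texture-GT
composition, positional learning, attention gating) rather than clinical
performance.

## 6. The reference study and problem sizes

The standard study trains the four-row ladder — vanilla U-Net, reduced
U-Net, reduced + attentions, proposed (reduced + attentions +
zero-padding) — under one shared budget per seed, with medians over seeds
{0, 1, 2}. Problem sizes are chosen for a single CPU: depth-3 models (base
16 for vanilla, 8 for reduced), 96×96 crops, 24 training / 8 validation
images, batch 4, 45 epochs, Adam at a constant lr 1e-2. The budget is the
smallest (in a coarse epoch grid) at which every ladder member's pore
channel reaches the binarization scale on held-out data, i.e. all rows are
trained to workable convergence rather than compared mid-transient. The full-scale depth-5 models
are used (without training) for the exact parameter accounting. The
learning rate is deliberately aggressive because the regression target
lives on the 0–255 scale and the epoch budget is short; at much smaller
rates no model reaches the output magnitudes within budget and all
comparisons degenerate.

Reported quantities per row: trainable parameters, final training loss,
validation MSE against the texture GT, wrinkle/pore IoU against the
generator's exact fine masks, and pore false-positive pixels outside the
butterfly zone (every such pixel is spurious by construction).

## 7. Known limitations

* The autodiff engine supports exactly the operations these models need;
  stride-1 convolutions only, spatial dims must be divisible by
  2^(depth−1).
* MSE on 0–255 targets makes the wrinkle channel (large, dense targets)
  dominate the pore channel (small, sparse targets) in the gradient; the
  pore task is correspondingly harder at short budgets.
* The wrinkle texture map has a high baseline (255/(1+c) ≥ 127.5 on any
  constant region), so the default pre-multiplication cutoff of 64 is
  permissive; the discriminative signal comes from the annotation mask and
  the map's relative modulation, not from the cutoff.
* Binarization thresholds (64/32) and the pore-map scaling constant
  (t_max = 0.25) are package conventions; the upstream formulation leaves
  them unspecified.
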