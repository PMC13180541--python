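# Methods

This note records the models implemented in `lesiondetr`, the assumptions
behind them, the knobs that matter, and the choices made where the design
was genuinely open.

## Problem setting

The library targets lesion detection in 2D brain MRI slices: four
categories (no tumor, meningioma, glioma, pituitary adenoma), one
annotation box per finding, and the clinical difficulties that make this
harder than natural-image detection — low lesion-to-tissue contrast,
indistinct boundaries, and irregular morphology.  The detector family is
the NMS-free real-time detection transformer: backbone → hybrid encoder
(intra-scale attention on the top pyramid level + cross-scale fusion) →
top-K query selection → cross-attention decoder → set prediction heads,
trained with one-to-one Hungarian matching so that no non-maximum
suppression is needed at inference.

Everything runs on CPU on top of a small reverse-mode autodiff engine
(`lesiondetr.nn`) written on NumPy: tape-based `Tensor`, im2col
convolutions, fused layer-norm/softmax primitives, and AdamW.  Every
primitive with a hand-written gradient is validated against central
finite differences in the test suite.

## The three bespoke operators

### Gated-CNN CSP backbone (`mambaout_csp`)

Token mixer: `y = x + σ(W_g·Norm(x)) ∘ conv(W_f·Norm(x))` with `Norm` a
channel layer norm, `W_g`/`W_f` pointwise maps, `conv` a 7×7 depthwise
convolution, `σ` the logistic sigmoid and `∘` the Hadamard product.  The
sigmoid gate performs per-position feature selection; there is no
state-space mixer.  At the default expansion ratio 1 the block is exactly
this equation (the residual decomposition `y − x = gate ∘ feature` is a
test); an expansion ratio > 1 widens both branches and adds a 1×1
projection back.

Stages wrap the blocks in a cross-stage-partial layout: entry conv
(stride 2 when downsampling), a 50/50 channel split into an untouched
shortcut and a processed branch, concat, 1×1 fuse.  Stem stride 4, four
stages at strides (1, 2, 2, 2); S3/S4/S5 tap the last three stages at
strides 8/16/32.  Full-scale widths (48, 96, 192, 288) at depths
(2, 2, 6, 2) put the backbone in the lightweight regime relative to the
residual baseline; the desk-scale preset shrinks widths and depths.  The
baseline backbone is the classic two-conv residual ("basic block")
design, depths (2, 2, 2, 2), widths (64, 128, 256, 512).

### Magnitude-aware linear attention (`mala`, `rope_decay`)

Linear attention with the positive kernel `φ(x) = ELU(x) + 1` computes
`φ(Q)[φ(K)ᵀV]` in O(N·d²), but the kernel map discards query magnitude,
flattening the score distribution — harmful when lesions are identified
by signal-amplitude differences.  The corrected core is

    z   = φ(Q̂) · mean_i φ(K̂)_i
    out = φ(Q̂)[φ(K̂)ᵀV] ⊙ (1 + (z + ε)⁻¹) − z ⊙ mean_i V_i ,  ε = 1e-6

with Q̂, K̂ the rotary-encoded queries/keys.  The mean is taken over the
*kernel-mapped, rotated* keys so `z > 0` always and the correction factor
is bounded; under that reading the single-position closed form is
`out = z/(z+ε)·V` (a test).  No N×N matrix is ever materialized (the
tests account peak intermediate sizes).  There is deliberately no
`φ(Q)Σφ(K)` denominator: the correction factor plays that role.

Rotary encoding: each head's channels split row-half/column-half;
consecutive channel pairs rotate as complex numbers by `pos · ω_i` with
the inverse-power ladder `ω_i = base^(−2i/(d/2))`, `base = 10000`, equal
frequencies on both axes by default.  The map is implemented as a true
rotation `(a,b) ↦ (a cosθ − b sinθ, a sinθ + b cosθ)` — the only form
for which inner products depend on relative offsets alone, which the
tests verify over random trials.

The full intra-scale block adds a 5×5 depthwise local positional
perturbation of V, a pointwise multiplicative gate O (from the same fused
1×1 QKVO projection), a 1×1 output projection, and the post-norm update
`LN(X + LN(Y + FFN(Y)))` with a two-layer GELU FFN.  Layer norm of a zero
vector with zero bias is 0 (variance floor 1e-5).  The block is applied
to S5 only; the ablation baseline in the same slot is a plain pre-norm
multi-head softmax block.

### Manhattan-decay retention (`retention`)

Manhattan self-attention masks softmax scores elementwise with
`D[n,m] = γ^(|x_n−x_m|+|y_n−y_m|)` and does **not** renormalize rows
afterwards (retention convention).  `D` factorizes exactly as
`d_row ⊗ d_col`, so the decomposed variant runs a per-row attention
masked by `d_col` followed by a per-column attention masked by `d_row` —
linear cost per axis, identical to the full operator on single-row/column
grids and an approximation elsewhere (they are different operators by
construction; order fixed as horizontal-then-vertical).  Per-head decay
rates follow the ladder `γ_i = 1 − 2^(−5−i)`.

`RetBlock` composes decomposed MaSA (rotary-encoded Q/K) with a 5×5
depthwise local-context enhancement of V in a pre-norm transformer block
(FFN ratio 2).  `RetBlockC3` is the aggregation block: 1×1 conv → n
RetBlocks on one path, 1×1 shortcut on the other, summed (no trailing
activation; the reference design is figure-only and addition-then-nothing
was chosen).  The baseline `RepC3` sums a stack of 3×3 convolutions with
a batch-normalized shortcut and applies SiLU.

## Detector assembly (`model_zoo`)

Pyramid features are projected to the hidden width (1×1 conv + channel
LN), the intra-scale block runs on S5, and the cross-scale fusion runs
top-down then bottom-up with one aggregation block at each of the four
fusion points (inputs concatenated at 2×hidden, blocks reduce back to
hidden).  Tokens from all three fused scales get a fixed sinusoidal
position embedding; a linear score head ranks them and the top-K become
decoder queries (ties broken by token index).  Query selection is trained
by an IoU-aware term folded into the loss: binary cross-entropy of the
token score against the max IoU between the token's anchor box and the
ground truth.  Each token carries an anchor (cell center,
scale-dependent size 0.05·2^level); the box head predicts logit offsets
added to the inverse-sigmoid of the anchor, so boxes start exactly at
their anchors (zero-initialized final layer).  The decoder is a standard
pre-norm stack of self-attention, cross-attention and FFN over the
selected queries — deliberately simple, with no deformable attention.

Loss: focal binary cross-entropy over classes (α = 0.25, γ = 2,
class-head bias initialized to the 1% prior), L1 and (1 − GIoU) on
matched pairs, weights (2, 5, 2), normalized by the number of matches;
the same loss is applied to every decoder layer (deep supervision) and
averaged.  Matching uses `scipy.optimize.linear_sum_assignment` on the
cost `2·(−p_cls) + 5·L1 + 2·(1−GIoU)`.

Training: AdamW (default lr 1e-4, weight decay 1e-4 — the reference
hyperparameter table omits the learning rate, so the default is this
library's choice), batch 8, horizontal flip with probability 0.5 as the
only augmentation, linear warmup over the first 100 steps, gradient-norm
clip 1.0, early stopping on validation mAP@50 with patience 10.
Inference keeps, per query, the max class probability as the score; no
NMS is applied.

## Synthetic phantoms (`phantom_data`)

The generator emulates the statistical structure of public four-class
brain-MRI detection sets: class weights proportional to
(880, 1738, 1408, 1705); an elliptical head with smooth tissue texture
and a bright rim; one lesion per image with a class-specific signature —
pituitary: small regular ellipse near the lower center; meningioma:
well-defined ellipse attached to the rim; glioma: irregular radial-
polygon blob with strong boundary blur (σ up to ~3 px) and internal
texture; no tumor: no lesion, annotated with a whole-image box so the
class participates in detection metrics (the reference evaluation
reports per-class mAP for the no-tumor category, which requires *some*
box convention; whole-image is this library's choice).  Boxes are the
tight boxes of the blurred lesion mask thresholded at half the lesion
contrast — derived from the clean mask, never from rendered pixels.
Noise is Rician (`|signal + complex Gaussian|`), the magnitude-MRI
standard.  Default knobs: contrast offset 0.15–0.35 of dynamic range,
boundary blur σ 0.5–2.5 px, heterogeneity amplitude 0.08, noise σ 0.03.

What the phantoms do **not** model: real MR physics, T1/T2/FLAIR
contrast mechanisms, 3D anatomy, multiple lesions per image, scanner
artifacts.  Tests passing on phantoms demonstrate that the operators,
training loop and metrics behave as specified — not that the detector
reaches clinical accuracy on real MRI.

## Metrics, profiling, explainability (`metrics_xai`)

COCO conventions: greedy score-ordered matching (one match per ground
truth, same class, IoU ≥ threshold), 101-point max-interpolated AP,
thresholds 0.50:0.05:0.95, mAP@50 and mAP@50–95 as means over classes
(classes with neither ground truth nor detections are excluded as
undefined).  P/R are reported at IoU 0.50 for detections above a 0.25
confidence operating point (the reference operating point is unstated
upstream; 0.25 is this library's documented default).  The profiler
counts trainable parameters exactly and multiply–accumulates by
layer-type accounting inside the dense primitives; GFLOPs = 2·MACs.

Grad-CAM: the top 2% of queries by confidence define the objective
(sum of max class logit + box regression outputs), gradients are taken
at named modules (default: the three cross-scale fusion outputs), each
channel weighted by its spatial mean gradient, rectified, min–max
normalized (all-zero maps stay zero), bilinearly upsampled.

## Scaled-down end-to-end benchmark

`scaled_two_class_benchmark(seed)` trains a reduced-width improved
variant (hidden 32, 2 heads, 20 queries, 2 decoder layers, backbone
widths 16/24/32/48) on 400 two-class 96×96 phantoms (meningioma +
pituitary — the two most morphologically distinct signatures) for at
most 30 epochs and reports mAP@50 on 100 held-out phantoms.  The step
size for this preset is 3e-4: the reduced parameterization tolerates a
larger step, and with warmup it converges well inside the epoch budget.
Problem sizes throughout the tests (96×96 images, reduced widths, short
schedules) are chosen so the whole suite runs on a single CPU in
minutes.

## Numerical choices and degenerate inputs

- float32 parameters and activations for training; oracle tests install
  float64 weights where 1e-5/1e-6 tolerances are asserted.
- `ε = 1e-6` in the attention correction; layer-norm variance floor 1e-5;
  GIoU denominators guarded by 1e-9; focal log arguments clipped by 1e-8.
- Ties in query selection and detection sorting break by index (stable
  sorts throughout).
- Degenerate boxes (zero width/height) are validation errors in the
  metrics; zero-contrast lesions still carry mask-derived boxes; empty
  label files mean "no findings".
- `masa_full` refuses grids above 4096 positions and points to the
  decomposed path.

## Known limitations

- The decomposed retention operator is not the full operator on general
  2D grids; only the direction of its cost/quality trade-off is tested.
- Training determinism holds because every kernel here is deterministic
  single-threaded NumPy; on BLAS builds with nondeterministic reductions
  the loss trajectories could differ in the last bits.
- The decoder is a plain cross-attention stack; no deformable attention,
  denoising queries, EMA, mosaic/HSV augmentation, or pretrained weights.
- Exact full-scale parameter totals of the reference architecture are
  not reproducible because its stage depths/widths are unpublished; only
  the lightweighting *direction* (fewer parameters and MACs than the
  baseline, near-parity for the intra-scale swap) is asserted.
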