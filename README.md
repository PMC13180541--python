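# lesiondetr

Detection transformers for low-contrast lesion detection in 2D brain MRI,
built to run — and be fully testable — on a single CPU.

Brain-tumor detection in MRI is hard for generic detectors: lesions sit at
low contrast against normal tissue, their boundaries blur into it, and
classes like glioma are morphologically irregular. This library implements
an NMS-free real-time detection-transformer pipeline specialised for that
setting, with three bespoke operators and their ablation baselines:

- **Gated-CNN CSP backbone** — token mixer
  `y = x + σ(W_g·Norm(x)) ∘ conv(W_f·Norm(x))` inside cross-stage-partial
  stages (channel split, gated main branch, shortcut, fuse); baseline: a
  ResNet18-style residual backbone.
- **Magnitude-aware linear attention (MALA)** for intra-scale interaction
  on the top pyramid level: linear attention with kernel `φ = ELU + 1`
  plus a correction restoring query-magnitude sensitivity,

      z = φ(Q̂)·mean φ(K̂),   out = φ(Q̂)[φ(K̂)ᵀV] ⊙ (1 + (z+ε)⁻¹) − z ⊙ V̄,

  with 2D axial rotary position encoding on Q, K, a depthwise local
  positional term, a multiplicative output gate, and a post-norm GELU FFN;
  baseline: plain multi-head softmax attention.
- **Manhattan-decay retention aggregation (RetBlockC3)** for cross-scale
  fusion: softmax attention masked elementwise by
  `D[n,m] = γ^(|Δrow|+|Δcol|)` (no renormalization), decomposed into
  per-row and per-column 1D passes at linear cost, with depthwise local
  context enhancement; baseline: RepC3 (conv stack + batch-norm shortcut
  + SiLU).

Around them: a seeded synthetic MRI-phantom generator (four classes with
realistic class imbalance, low-contrast lesions, Rician noise, YOLO-txt /
COCO-JSON round-trips), set-prediction training with Hungarian matching
and focal/L1/GIoU losses, COCO-style evaluation (P, R, AP, mAP@50,
mAP@50–95), an exact parameter/MAC profiler over the 2³ module-toggle
ablation grid, and Grad-CAM for the fusion outputs. All neural operators
run on a small NumPy reverse-mode autodiff core shipped in
`lesiondetr.nn` and validated against finite differences.

## Worked example

Generate a small phantom dataset (class mix follows the 880/1738/1408/1705
imbalance of the public four-class brain-MRI collection):

```sh
$ lesiondetr generate -o demo/data --n 16 --seed 0
no_tumor        1
meningioma      7
glioma          6
pituitary       2
```

Profile the full ablation grid at 96×96 (parameters and
multiply–accumulates; the improved corner is the lightest in both):

```sh
$ lesiondetr profile --image-size 96
backbone	intra_scale	aggregation	params	macs
resnet18	aifi_mhsa	repc3	1078057	80007360
resnet18	aifi_mhsa	retblockc3	955433	73554432
resnet18	aifi_mala	repc3	1083817	80066688
resnet18	aifi_mala	retblockc3	961193	73613760
cspmambaout	aifi_mhsa	repc3	729353	48186024
cspmambaout	aifi_mhsa	retblockc3	606729	41733096
cspmambaout	aifi_mala	repc3	735113	48245352
cspmambaout	aifi_mala	retblockc3	612489	41792424
```

Swapping in the gated-CSP backbone and retention aggregation cuts
parameters by ~43% and MACs by ~48% at this scale, while the MALA swap is
near parameter parity (+0.5%) — the lightweighting pattern the three
operators are designed for. Train and evaluate:

```sh
lesiondetr train --data-dir demo/data -o demo/run --epochs 5
lesiondetr eval  --data-dir demo/data --checkpoint demo/run/checkpoint.npz -o demo/eval
lesiondetr cam   --checkpoint demo/run/checkpoint.npz -o demo/cam demo/data/images/000000.png
```

The metric module can also be used directly; here a constructed fixture
where every detection overlaps its ground truth at IoU exactly 0.62, so
it passes the 0.50–0.60 thresholds and fails 0.65 upward:

```python
import numpy as np
from lesiondetr.metrics_xai import evaluate

w, a = 81.0, 19.0  # IoU = (w-a)/(w+a) = 0.62
gts  = [{"boxes": np.array([[0.0, 0.0, w, 1.0]]), "classes": np.array([0])}
        for _ in range(10)]
dets = [{"boxes": np.array([[a, 0.0, w + a, 1.0]]), "scores": np.array([0.9]),
         "classes": np.array([0])} for _ in range(10)]
res = evaluate(dets, gts, classes=[0])
print(f"mAP@50    = {res.map50:.3f}")      # mAP@50    = 1.000
print(f"mAP@50-95 = {res.map50_95:.3f}")   # mAP@50-95 = 0.300
```

Three of the ten IoU thresholds accept the boxes, so the averaged mAP is
exactly 3/10.

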