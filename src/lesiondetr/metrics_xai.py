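"""Detection metrics (P, R, AP, mAP), model profiling, and Grad-CAM.

Metrics follow the COCO conventions: greedy score-ordered matching with
one match per ground-truth box, 101-point max-interpolated average
precision, the IoU threshold grid 0.50:0.05:0.95, precision
``P = TP / (TP + FP)`` and recall ``R = TP / (TP + FN)`` at IoU 0.50 for
all detections above a confidence operating point (0.25 by default).

Profiling reports the exact trainable-parameter count and a
multiply-accumulate count from layer-type accounting during one forward
pass (GFLOPs, when printed, are ``2 * MACs``).

Grad-CAM backpropagates a joint objective over the top-confidence
detections — max class logit plus the box regression outputs — and
weights each target activation channel by the spatial mean of its
gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import nn

__all__ = [
    "box_iou",
    "iou_matrix",
    "match_detections",
    "average_precision",
    "evaluate",
    "EvalResult",
    "profile",
    "grad_cam",
    "IOU_GRID",
]

IOU_GRID = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))
_RECALL_GRID = np.linspace(0.0, 1.0, 101)


def box_iou(a, b) -> float:
    """IoU of two 0-based half-open pixel xyxy boxes."""
    ax1, ay1, ax2, ay2 = map(float, a)
    bx1, by1, bx2, by2 = map(float, b)
    if ax2 <= ax1 or ay2 <= ay1 or bx2 <= bx1 or by2 <= by1:
        raise ValueError(f"degenerate box: {a if ax2 <= ax1 or ay2 <= ay1 else b}")
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU for (N, 4) and (M, 4) xyxy arrays."""
    a = np.asarray(a, dtype=float).reshape(-1, 4)
    b = np.asarray(b, dtype=float).reshape(-1, 4)
    iw = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    ih = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def match_detections(
    det_boxes: np.ndarray,
    det_classes: np.ndarray,
    gt_boxes: np.ndarray,
    gt_classes: np.ndarray,
    iou_thr: float,
) -> tuple[np.ndarray, int]:
    """Greedy matching of score-sorted detections to ground truth.

    Each detection, in order, claims the highest-IoU unmatched same-class
    ground-truth box with IoU >= threshold.  Returns the per-detection
    TP flags and the count of unmatched ground-truth boxes (FN).
    """
    n_det = len(det_boxes)
    n_gt = len(gt_boxes)
    tp = np.zeros(n_det, dtype=bool)
    taken = np.zeros(n_gt, dtype=bool)
    if n_det and n_gt:
        ious = iou_matrix(det_boxes, gt_boxes)
        for i in range(n_det):
            candidates = (
                (gt_classes == det_classes[i]) & ~taken & (ious[i] >= iou_thr)
            )
            if candidates.any():
                j = int(np.argmax(np.where(candidates, ious[i], -1.0)))
                taken[j] = True
                tp[i] = True
    return tp, int(n_gt - taken.sum())


def average_precision(tp_flags: np.ndarray, scores: np.ndarray, num_gt: int) -> float | None:
    """101-point interpolated AP.

    Returns ``None`` (undefined, excluded from means) when there is
    neither ground truth nor any detection for the class; 0.0 when
    detections exist but no ground truth does.
    """
    tp_flags = np.asarray(tp_flags, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if num_gt == 0:
        return None if len(tp_flags) == 0 else 0.0
    if len(tp_flags) == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    tp = tp_flags[order].astype(float)
    fp = 1.0 - tp
    ctp = np.cumsum(tp)
    cfp = np.cumsum(fp)
    recall = ctp / num_gt
    precision = ctp / np.maximum(ctp + cfp, 1e-12)
    # max precision to the right of each recall level
    p_interp = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    for r in _RECALL_GRID:
        mask = recall >= r - 1e-12
        ap += p_interp[mask][0] if mask.any() else 0.0
    return ap / len(_RECALL_GRID)


@dataclass
class EvalResult:
    """Per-class counts, P/R at the reference threshold, AP tables, mAPs."""

    classes: list[int]
    iou_thresholds: tuple[float, ...]
    ap: dict[int, dict[float, float | None]]
    tp: dict[int, dict[float, int]]
    fp: dict[int, dict[float, int]]
    fn: dict[int, dict[float, int]]
    precision: dict[int, float]
    recall: dict[int, float]
    map50: float
    map50_95: float
    score_threshold: float = 0.25

    def table(self) -> str:
        """Machine-readable TSV: class rows, per-threshold AP columns."""
        header = "class\tP\tR\t" + "\t".join(f"AP@{t:.2f}" for t in self.iou_thresholds)
        rows = [header]
        for c in self.classes:
            aps = "\t".join(
                "nan" if self.ap[c][t] is None else f"{self.ap[c][t]:.4f}"
                for t in self.iou_thresholds
            )
            rows.append(f"{c}\t{self.precision[c]:.4f}\t{self.recall[c]:.4f}\t{aps}")
        rows.append(f"mAP@50\t{self.map50:.4f}")
        rows.append(f"mAP@50-95\t{self.map50_95:.4f}")
        return "\n".join(rows)


def evaluate(
    detections: list[dict],
    ground_truths: list[dict],
    classes: list[int] | None = None,
    score_threshold: float = 0.25,
) -> EvalResult:
    """Evaluate per-image detections against ground truth.

    ``detections[i]`` / ``ground_truths[i]`` describe image ``i`` as dicts
    with keys ``boxes`` (N, 4 pixel xyxy), ``classes`` (N,), and for
    detections also ``scores`` (N,).  AP is computed per class at each
    threshold in the 0.50:0.05:0.95 grid using all detections; P and R use
    IoU 0.50 and the confidence operating point ``score_threshold``.
    """
    if len(detections) != len(ground_truths):
        raise ValueError("detections and ground_truths must align per image")
    if classes is None:
        classes = sorted(
            {int(c) for g in ground_truths for c in np.asarray(g["classes"]).reshape(-1)}
        )
    all_gt_classes = [int(c) for g in ground_truths for c in np.asarray(g["classes"]).reshape(-1)]
    all_det_classes = [int(c) for d in detections for c in np.asarray(d["classes"]).reshape(-1)]
    known = set(classes)
    for c in all_gt_classes + all_det_classes:
        if c not in known:
            raise ValueError(f"class id {c} outside the evaluated set {sorted(known)}")

    ap: dict[int, dict[float, float | None]] = {c: {} for c in classes}
    tp_c: dict[int, dict[float, int]] = {c: {} for c in classes}
    fp_c: dict[int, dict[float, int]] = {c: {} for c in classes}
    fn_c: dict[int, dict[float, int]] = {c: {} for c in classes}
    precision: dict[int, float] = {}
    recall: dict[int, float] = {}

    for c in classes:
        num_gt = sum(
            int((np.asarray(g["classes"]).reshape(-1) == c).sum()) for g in ground_truths
        )
        for thr in IOU_GRID:
            flags_all: list[np.ndarray] = []
            scores_all: list[np.ndarray] = []
            tp_ref = fp_ref = fn_ref = 0
            for det, gt in zip(detections, ground_truths):
                d_boxes = np.asarray(det["boxes"], dtype=float).reshape(-1, 4)
                d_cls = np.asarray(det["classes"], dtype=int).reshape(-1)
                d_scores = np.asarray(det["scores"], dtype=float).reshape(-1)
                g_boxes = np.asarray(gt["boxes"], dtype=float).reshape(-1, 4)
                g_cls = np.asarray(gt["classes"], dtype=int).reshape(-1)
                sel = d_cls == c
                gsel = g_cls == c
                order = np.argsort(-d_scores[sel], kind="stable")
                db = d_boxes[sel][order]
                ds = d_scores[sel][order]
                flags, _ = match_detections(
                    db, np.full(sel.sum(), c), g_boxes[gsel], g_cls[gsel], thr
                )
                flags_all.append(flags)
                scores_all.append(ds)
                # reference operating point for P/R
                keep = ds >= score_threshold
                f_ref, fn_i = match_detections(
                    db[keep], np.full(int(keep.sum()), c), g_boxes[gsel], g_cls[gsel], thr
                )
                tp_ref += int(f_ref.sum())
                fp_ref += int((~f_ref).sum())
                fn_ref += fn_i
            flags = np.concatenate(flags_all) if flags_all else np.zeros(0, bool)
            scores = np.concatenate(scores_all) if scores_all else np.zeros(0)
            ap[c][thr] = average_precision(flags, scores, num_gt)
            tp_c[c][thr] = tp_ref
            fp_c[c][thr] = fp_ref
            fn_c[c][thr] = fn_ref
            if thr == 0.50:
                denom_p = tp_ref + fp_ref
                denom_r = tp_ref + fn_ref
                precision[c] = tp_ref / denom_p if denom_p else 0.0
                recall[c] = tp_ref / denom_r if denom_r else 0.0

    def _mean(values: list[float | None]) -> float:
        defined = [v for v in values if v is not None]
        return float(np.mean(defined)) if defined else 0.0

    map50 = _mean([ap[c][0.50] for c in classes])
    map50_95 = _mean([ap[c][t] for c in classes for t in IOU_GRID])
    return EvalResult(
        classes=list(classes),
        iou_thresholds=IOU_GRID,
        ap=ap,
        tp=tp_c,
        fp=fp_c,
        fn=fn_c,
        precision=precision,
        recall=recall,
        map50=map50,
        map50_95=map50_95,
        score_threshold=score_threshold,
    )


# ---------------------------------------------------------------------------
# profiling
# ---------------------------------------------------------------------------


def profile(model: nn.Module, input_size: int, in_channels: int = 3) -> dict:
    """Exact parameter count plus MACs accounted during one forward pass."""
    params = model.num_parameters()
    was_training = model.training
    model.eval()
    x = nn.Tensor(np.zeros((1, in_channels, input_size, input_size)))
    with nn.MacCounter() as counter, nn.no_grad():
        model(x)
    if was_training:
        model.train()
    return {
        "params": params,
        "macs": counter.macs,
        "params_millions": params / 1e6,
        "gflops": 2.0 * counter.macs / 1e9,
    }


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------


def grad_cam(
    model,
    image: np.ndarray,
    target_modules: list[str],
    top_fraction: float = 0.02,
) -> dict[str, np.ndarray]:
    """Class-activation heatmaps for a detector on one grayscale image.

    The objective sums, over the ``ceil(top_fraction * num_queries)``
    highest-confidence detections, the max class logit plus the box
    regression outputs; its gradient is taken at the named modules'
    activations.  Channel weights are spatial gradient means; the weighted
    sum is rectified, min–max normalized to [0, 1] (all-zero maps stay
    zero), and upsampled to the image size.
    """
    named = dict(model.named_modules())
    for name in target_modules:
        if name not in named:
            raise ValueError(
                f"unknown target module '{name}'; available: {sorted(named)[:20]}..."
            )
    model.eval()
    for name in target_modules:
        named[name]._cam_capture = True
        named[name]._cam_activation = None
    try:
        logits, boxes = model.forward_raw(_prep_image(image))
    finally:
        for name in target_modules:
            named[name]._cam_capture = False
    # top-confidence queries
    num_queries = logits.shape[1]
    k = max(1, math.ceil(top_fraction * num_queries))
    conf = logits.data.max(axis=-1)[0]  # batch of 1
    top = np.argsort(-conf, kind="stable")[:k]
    objective = (logits[0, top].max(axis=-1)).sum() + boxes[0, top].sum()
    model.zero_grad()
    objective.backward()
    H, W = image.shape[-2:]
    heatmaps: dict[str, np.ndarray] = {}
    for name in target_modules:
        act = getattr(named[name], "_cam_activation", None)
        if act is None or act.grad is None:
            raise ValueError(f"module '{name}' produced no stored activation")
        weights = act.grad.mean(axis=(2, 3), keepdims=True)  # (1, C, 1, 1)
        cam = np.maximum((weights * act.data).sum(axis=1)[0], 0.0)
        if cam.max() > 0:
            cam = (cam - cam.min()) / (cam.max() - cam.min())
        heatmaps[name] = np.clip(
            ndimage.zoom(cam, (H / cam.shape[0], W / cam.shape[1]), order=1), 0.0, 1.0
        )
    return heatmaps


def _prep_image(image: np.ndarray) -> nn.Tensor:
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = np.repeat(img[None], 3, axis=0)
    return nn.Tensor(img[None])
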