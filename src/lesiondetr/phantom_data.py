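"""Seeded synthetic MRI-like phantoms with low-contrast lesions.

Real brain-tumor MRI detection sets are large and not redistributable, so
this module generates structurally similar stand-ins: an elliptical
"brain" with smooth tissue texture, one lesion per image drawn according
to a class-specific signature, Rician magnitude noise, and bounding boxes
derived from the *noiseless* lesion mask (never from the rendered pixels).

Class signatures (four classes, mirroring the common public MRI sets):

* ``no_tumor``    — no lesion; annotated with one whole-image box so that
  the class participates in detection metrics like the other three.
* ``meningioma``  — well-defined ellipse attached to the brain rim
  (dural-attachment-like position).
* ``glioma``      — irregular blob (perturbed radial polygon) with strong
  boundary blur and internal texture heterogeneity.
* ``pituitary``   — small regular ellipse near the lower-center (sellar
  region), crisp boundary.

Default class weights are proportional to (880, 1738, 1408, 1705) — the
class counts of the public four-class brain-tumor MRI collection this
generator emulates.

Boxes are stored normalized center-size (cx, cy, w, h) in (0, 1]; the
pixel convention everywhere in the library is 0-based, half-open xyxy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import draw as skdraw

__all__ = [
    "CLASS_NAMES",
    "PhantomConfig",
    "ImageSample",
    "generate_phantom",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

logger = logging.getLogger(__name__)

CLASS_NAMES = ("no_tumor", "meningioma", "glioma", "pituitary")
_DEFAULT_COUNTS = np.array([880.0, 1738.0, 1408.0, 1705.0])


@dataclass(frozen=True)
class PhantomConfig:
    """Generation knobs; same (config, seed) yields a byte-identical dataset."""

    image_size: int = 96
    class_weights: tuple[float, ...] = tuple(
        float(w) for w in _DEFAULT_COUNTS / _DEFAULT_COUNTS.sum()
    )
    contrast_range: tuple[float, float] = (0.15, 0.35)
    boundary_blur_range: tuple[float, float] = (0.5, 2.5)
    heterogeneity: float = 0.08
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.class_weights, dtype=float)
        if w.shape != (4,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(
                "class_weights must be 4 non-negative values summing to 1"
            )
        if self.image_size < 16:
            raise ValueError(f"image_size must be >= 16, got {self.image_size}")
        if self.contrast_range[0] < 0 or self.boundary_blur_range[0] < 0:
            raise ValueError("contrast and blur ranges must be non-negative")


@dataclass
class ImageSample:
    """One grayscale image in [0, 1] plus its annotations.

    ``boxes`` is a list of ``(class_id, cx, cy, w, h)`` with coordinates as
    fractions of the image side.
    """

    image: np.ndarray
    boxes: list[tuple[int, float, float, float, float]]
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("image values must lie in [0, 1]")
        for cid, cx, cy, w, h in self.boxes:
            if not (0 <= cid <= 3):
                raise ValueError(f"class_id {cid} outside [0, 3]")
            if w <= 0 or h <= 0:
                raise ValueError("box width/height must be positive")
            if cx - w / 2 < -1e-9 or cx + w / 2 > 1 + 1e-9:
                raise ValueError("box exceeds unit square horizontally")
            if cy - h / 2 < -1e-9 or cy + h / 2 > 1 + 1e-9:
                raise ValueError("box exceeds unit square vertically")


def _brain_background(size: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Elliptical head with smooth tissue texture; returns (image, brain mask)."""
    cy, cx = size / 2, size / 2
    ry = size * rng.uniform(0.36, 0.42)
    rx = size * rng.uniform(0.30, 0.36)
    rot = rng.uniform(-0.2, 0.2)
    rr, cc = skdraw.ellipse(cy, cx, ry, rx, shape=(size, size), rotation=rot)
    mask = np.zeros((size, size), bool)
    mask[rr, cc] = True
    tissue = rng.normal(0.0, 1.0, (size, size))
    tissue = ndimage.gaussian_filter(tissue, sigma=size / 16)
    tissue = 0.05 * tissue / (np.abs(tissue).max() + 1e-12)
    img = np.where(mask, 0.45 + tissue, 0.02)
    # soft skull rim
    rim = mask & ~ndimage.binary_erosion(mask, iterations=max(1, size // 48))
    img[rim] = 0.75
    return img.astype(float), mask


def _lesion_mask(
    class_name: str, size: int, brain: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Binary (pre-blur) lesion mask per class signature; returns (mask, blur sigma)."""
    mask = np.zeros((size, size), bool)
    if class_name == "pituitary":
        # small, regular ellipse near the lower-center (sellar region)
        cy = size * rng.uniform(0.60, 0.70)
        cx = size * rng.uniform(0.45, 0.55)
        r = size * rng.uniform(0.05, 0.09)
        rr, cc = skdraw.ellipse(cy, cx, r, r * rng.uniform(0.8, 1.1), shape=(size, size))
        mask[rr, cc] = True
        blur = rng.uniform(0.0, 0.5)  # crisp boundary
    elif class_name == "meningioma":
        # well-defined ellipse touching the brain rim
        theta = rng.uniform(0, 2 * np.pi)
        # place center just inside the rim of the brain mask along direction theta
        ys, xs = np.nonzero(brain)
        cy0, cx0 = ys.mean(), xs.mean()
        # march outward until leaving the brain
        step = np.arange(size)
        py = cy0 + step * np.sin(theta)
        px = cx0 + step * np.cos(theta)
        inside = [
            i
            for i, (y, x) in enumerate(zip(py, px))
            if 0 <= int(y) < size and 0 <= int(x) < size and brain[int(y), int(x)]
        ]
        edge = inside[-1] if inside else size // 4
        r = size * rng.uniform(0.07, 0.12)
        cy = cy0 + (edge - r * 0.8) * np.sin(theta)
        cx = cx0 + (edge - r * 0.8) * np.cos(theta)
        rr, cc = skdraw.ellipse(
            cy, cx, r, r * rng.uniform(0.7, 1.0), shape=(size, size),
            rotation=rng.uniform(0, np.pi),
        )
        mask[rr, cc] = True
        blur = rng.uniform(0.0, 0.8)
    elif class_name == "glioma":
        # irregular blob: radial polygon with perturbed radii
        cy = size * rng.uniform(0.35, 0.6)
        cx = size * rng.uniform(0.35, 0.65)
        base_r = size * rng.uniform(0.08, 0.14)
        angles = np.linspace(0, 2 * np.pi, 14, endpoint=False)
        radii = base_r * rng.uniform(0.5, 1.5, size=angles.size)
        rr, cc = skdraw.polygon(
            cy + radii * np.sin(angles), cx + radii * np.cos(angles), shape=(size, size)
        )
        mask[rr, cc] = True
        blur = rng.uniform(1.0, 3.0)  # indistinct boundary
    mask &= brain if class_name != "meningioma" else np.ones_like(brain)
    return mask, float(blur)


def generate_phantom(config: PhantomConfig, rng: np.random.Generator) -> ImageSample:
    """Draw one phantom; the class is sampled from ``config.class_weights``.

    The bounding box is the tight box of the blurred lesion mask
    thresholded at half the lesion contrast level — i.e. derived from the
    clean mask before any noise is applied, so a zero-contrast lesion still
    carries its mask-derived box.
    """
    size = config.image_size
    class_id = int(rng.choice(4, p=np.asarray(config.class_weights, dtype=float)))
    class_name = CLASS_NAMES[class_id]
    img, brain = _brain_background(size, rng)
    boxes: list[tuple[int, float, float, float, float]] = []
    meta: dict = {"class_id": class_id, "class_name": class_name}

    if class_name == "no_tumor":
        boxes.append((class_id, 0.5, 0.5, 1.0, 1.0))
        meta.update(contrast=0.0, blur=0.0, lesion_area=0)
    else:
        mask, blur = _lesion_mask(class_name, size, brain, rng)
        lo, hi = config.boundary_blur_range
        blur = float(np.clip(blur, lo, hi))
        contrast = float(rng.uniform(*config.contrast_range))
        soft = mask.astype(float)
        if blur > 0:
            soft = ndimage.gaussian_filter(soft, sigma=blur)
        # half-contrast threshold on the (contrast-scaled) mask == 0.5 on soft
        support = soft >= 0.5
        if not support.any():  # heavily blurred tiny lesion: fall back to raw mask
            support = mask
        ys, xs = np.nonzero(support)
        x1, x2 = xs.min(), xs.max() + 1  # half-open
        y1, y2 = ys.min(), ys.max() + 1
        boxes.append(
            (
                class_id,
                (x1 + x2) / 2 / size,
                (y1 + y2) / 2 / size,
                (x2 - x1) / size,
                (y2 - y1) / size,
            )
        )
        texture = np.zeros_like(soft)
        if config.heterogeneity > 0 and class_name == "glioma":
            texture = ndimage.gaussian_filter(
                rng.normal(0, 1, (size, size)), sigma=size / 24
            )
            texture = config.heterogeneity * texture / (np.abs(texture).max() + 1e-12)
        img = img + soft * (contrast + texture)
        meta.update(
            contrast=contrast,
            blur=blur,
            lesion_area=int(mask.sum()),
            support_mask=support,
        )

    if config.noise_sigma > 0:
        # Rician magnitude noise: |signal + complex Gaussian|
        n1 = rng.normal(0, config.noise_sigma, img.shape)
        n2 = rng.normal(0, config.noise_sigma, img.shape)
        img = np.hypot(img + n1, n2)
    img = np.clip(img, 0.0, 1.0)
    sample = ImageSample(image=img, boxes=boxes, meta=meta)
    sample.validate()
    return sample


def generate_dataset(config: PhantomConfig, n: int) -> list[ImageSample]:
    """Generate ``n`` seeded phantoms (deterministic in (config, n))."""
    rng = np.random.default_rng(config.seed)
    return [generate_phantom(config, rng) for _ in range(n)]


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------


def _to_u8(img: np.ndarray) -> np.ndarray:
    return np.round(img * 255.0).astype(np.uint8)


def write_dataset(
    samples: list[ImageSample],
    out_dir: str | Path,
    format: str = "yolo_txt",
    config: PhantomConfig | None = None,
) -> dict:
    """Write PNG images + annotations; returns (and writes) the manifest.

    ``yolo_txt``: one ``labels/<stem>.txt`` per image with lines
    ``class cx cy w h`` (normalized, 6-decimal fixed point) and a
    ``dataset.yaml``-style descriptor listing class names.
    ``coco_json``: a single ``annotations.json`` with 0-based top-left
    pixel ``[x, y, w, h]`` boxes.
    """
    if not samples:
        raise ValueError("samples must be non-empty")
    if format not in ("yolo_txt", "coco_json"):
        raise ValueError(f"unknown format '{format}' (yolo_txt or coco_json)")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    counts = [0, 0, 0, 0]
    coco: dict = {
        "images": [],
        "annotations": [],
        "categories": [
            {"id": i, "name": n} for i, n in enumerate(CLASS_NAMES)
        ],
    }
    ann_id = 0
    if format == "yolo_txt":
        (out / "labels").mkdir(exist_ok=True)
    for i, s in enumerate(samples):
        stem = f"{i:06d}"
        size = s.image.shape[0]
        Image.fromarray(_to_u8(s.image), mode="L").save(out / "images" / f"{stem}.png")
        for cid, *_ in s.boxes:
            counts[cid] += 1
        if format == "yolo_txt":
            lines = [
                f"{cid} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"
                for cid, cx, cy, w, h in s.boxes
            ]
            (out / "labels" / f"{stem}.txt").write_text(
                "\n".join(lines) + ("\n" if lines else "")
            )
        else:
            coco["images"].append(
                {"id": i, "file_name": f"images/{stem}.png", "width": size, "height": size}
            )
            for cid, cx, cy, w, h in s.boxes:
                coco["annotations"].append(
                    {
                        "id": ann_id,
                        "image_id": i,
                        "category_id": cid,
                        "bbox": [
                            (cx - w / 2) * size,
                            (cy - h / 2) * size,
                            w * size,
                            h * size,
                        ],
                        "area": w * size * h * size,
                        "iscrowd": 0,
                    }
                )
                ann_id += 1
    if format == "yolo_txt":
        (out / "dataset.yaml").write_text(
            "names:\n" + "".join(f"  {i}: {n}\n" for i, n in enumerate(CLASS_NAMES))
        )
    else:
        (out / "annotations.json").write_text(json.dumps(coco, indent=1))
    manifest = {
        "format": format,
        "num_images": len(samples),
        "class_names": list(CLASS_NAMES),
        "per_class_counts": counts,
        "config": asdict(config) if config else None,
        "seed": config.seed if config else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_dataset(in_dir: str | Path, format: str = "yolo_txt") -> list[ImageSample]:
    """Inverse of :func:`write_dataset`.

    A missing YOLO label file is treated as an image with zero boxes (the
    no-annotation convention) and logged; malformed label lines raise with
    file name and line number.
    """
    root = Path(in_dir)
    if format not in ("yolo_txt", "coco_json"):
        raise ValueError(f"unknown format '{format}' (yolo_txt or coco_json)")
    image_files = sorted((root / "images").glob("*.png"))
    if not image_files:
        raise FileNotFoundError(f"no images found under {root / 'images'}")
    samples = []
    if format == "coco_json":
        coco = json.loads((root / "annotations.json").read_text())
        by_image: dict[int, list] = {}
        sizes = {im["id"]: (im["width"], im["height"]) for im in coco["images"]}
        names = {im["id"]: im["file_name"] for im in coco["images"]}
        for ann in coco["annotations"]:
            by_image.setdefault(ann["image_id"], []).append(ann)
        for img_id in sorted(sizes):
            arr = (
                np.asarray(Image.open(root / names[img_id]), dtype=float) / 255.0
            )
            W, H = sizes[img_id]
            boxes = []
            for ann in by_image.get(img_id, []):
                cid = int(ann["category_id"])
                if not (0 <= cid <= 3):
                    raise ValueError(
                        f"{root / 'annotations.json'}: category_id {cid} out of range"
                    )
                x, y, w, h = ann["bbox"]
                boxes.append((cid, (x + w / 2) / W, (y + h / 2) / H, w / W, h / H))
            samples.append(ImageSample(image=arr, boxes=boxes))
        return samples
    for f in image_files:
        arr = np.asarray(Image.open(f), dtype=float) / 255.0
        label = root / "labels" / (f.stem + ".txt")
        boxes = []
        if not label.exists():
            logger.warning("missing label file %s; assuming zero boxes", label)
        else:
            for ln, line in enumerate(label.read_text().splitlines(), start=1):
                if not line.strip():
                    continue
                parts = line.split()
                if len(parts) != 5:
                    raise ValueError(f"{label}:{ln}: expected 5 fields, got {len(parts)}")
                try:
                    cid = int(parts[0])
                    cx, cy, w, h = map(float, parts[1:])
                except ValueError as e:
                    raise ValueError(f"{label}:{ln}: unparseable line: {line!r}") from e
                if not (0 <= cid <= 3):
                    raise ValueError(f"{label}:{ln}: class id {cid} out of range [0, 3]")
                boxes.append((cid, cx, cy, w, h))
        samples.append(ImageSample(image=arr, boxes=boxes))
    return samples
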