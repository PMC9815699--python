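"""Synthetic top-down field scenes with known crop/weed ground truth.

The generator emulates the statistics of an annotated sugarbeet field corpus:
a soil-coloured, lightly textured background; large, roundish green "crop"
plants; and small, irregular multi-lobed "weed" plants, at a heavily
unbalanced crop:weed object-count ratio (about 17:3 by default).  Images are
desk-scale (default 128x96) stand-ins for 1296x966 field frames: small enough
that every downstream stage — region growing, copy-paste augmentation,
training, evaluation — runs in seconds on one CPU.

Scenes carry exact ground truth: each painted object yields a tight
pixel-aligned bounding box stored in normalized YOLO center format
(``class cx cy w h``).  Vegetation is green-dominant by construction, so an
excess-green threshold (2G - R - B > 0) recovers painted plant pixels, which
is what makes the region-growing segmentation in :mod:`weeddet.augment`
meaningful on these scenes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

CROP, WEED = 0, 1

SOIL_RGB = (118, 84, 58)


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot honor placement constraints."""


@dataclass
class SceneParams:
    """Parameters of one synthetic field scene.

    ``weed_radius_range`` must lie strictly below ``crop_radius_range``: the
    crop/weed scale gap is the phenomenon the multi-scale fusion head is
    built for, so the generator enforces it.
    """

    image_size: tuple[int, int] = (192, 144)  # (width, height)
    n_crops: int = 17
    n_weeds: int = 3
    crop_radius_range: tuple[float, float] = (7.0, 10.0)
    weed_radius_range: tuple[float, float] = (2.5, 4.5)
    soil_texture_noise: float = 5.0
    vegetation_color_range: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] = (
        (30, 85),    # R
        (120, 210),  # G
        (20, 75),    # B
    )
    min_object_separation: float = 2.0
    seed: int = 0
    max_attempts: int = 400

    def __post_init__(self):
        if self.n_crops < 0 or self.n_weeds < 0:
            raise ValueError("object counts must be non-negative")
        if min(self.crop_radius_range) <= 0 or min(self.weed_radius_range) <= 0:
            raise ValueError("radius ranges must be positive")
        if max(self.weed_radius_range) >= min(self.crop_radius_range):
            raise ValueError(
                "weed_radius_range must lie strictly below crop_radius_range"
            )
        rl, gl, bl = self.vegetation_color_range
        # guarantee excess-green positivity: 2*G_min > R_max + B_max
        if 2 * gl[0] <= rl[1] + bl[1]:
            raise ValueError("vegetation color range must be green-dominant")


@dataclass
class AnnotatedImage:
    """An RGB scene plus YOLO-format ground truth and provenance."""

    pixels: np.ndarray                      # (H, W, 3) uint8
    boxes: list[tuple[int, float, float, float, float]]
    provenance: str = "original"            # "original" | "synthetic"
    source_id: str = ""
    image_id: str = ""
    object_masks: list[np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.provenance == "synthetic" and not self.source_id:
            raise ValueError("synthetic image requires a non-empty source_id")
        for cls, cx, cy, w, h in self.boxes:
            if not (0 < w <= 1 and 0 < h <= 1 and 0 <= cx <= 1 and 0 <= cy <= 1):
                raise ValueError(f"box out of range: {(cls, cx, cy, w, h)}")

    @property
    def size(self) -> tuple[int, int]:
        h, w = self.pixels.shape[:2]
        return w, h

    def pixel_boxes(self) -> np.ndarray:
        """Boxes as (class, x1, y1, x2, y2) in pixel corner coordinates."""
        w, h = self.size
        out = []
        for cls, cx, cy, bw, bh in self.boxes:
            out.append([cls, (cx - bw / 2) * w, (cy - bh / 2) * h,
                        (cx + bw / 2) * w, (cy + bh / 2) * h])
        return np.array(out, dtype=float).reshape(-1, 5)

    def class_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for cls, *_ in self.boxes:
            counts[cls] = counts.get(cls, 0) + 1
        return counts


def mask_to_normalized_box(mask: np.ndarray) -> tuple[float, float, float, float]:
    """Tight normalized (cx, cy, w, h) around the True pixels of ``mask``."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("empty mask has no bounding box")
    h, w = mask.shape
    x0, x1 = xs.min(), xs.max()
    y0, y1 = ys.min(), ys.max()
    bw, bh = (x1 - x0 + 1) / w, (y1 - y0 + 1) / h
    return ((x0 + x1 + 1) / 2 / w, (y0 + y1 + 1) / 2 / h, bw, bh)


def _ellipse_mask(shape: tuple[int, int], cx: float, cy: float, rx: float,
                  ry: float, theta: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    c, s = math.cos(theta), math.sin(theta)
    u = (dx * c + dy * s) / rx
    v = (-dx * s + dy * c) / ry
    return u * u + v * v <= 1.0


def _weed_mask(shape: tuple[int, int], cx: float, cy: float, r: float,
               rng: np.random.Generator) -> np.ndarray:
    """Small irregular plant: a union of 3-5 lobes around the center."""
    n_lobes = int(rng.integers(3, 6))
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_lobes):
        ang = rng.uniform(0, 2 * math.pi)
        off = rng.uniform(0.2, 0.6) * r
        lr = rng.uniform(0.35, 0.6) * r
        mask |= _ellipse_mask(shape, cx + off * math.cos(ang),
                              cy + off * math.sin(ang), lr,
                              lr * rng.uniform(0.6, 1.0),
                              rng.uniform(0, math.pi))
    # guarantee non-empty and centered
    mask |= _ellipse_mask(shape, cx, cy, max(r * 0.3, 1.0), max(r * 0.3, 1.0), 0.0)
    return mask


def _paint_vegetation(pixels: np.ndarray, mask: np.ndarray,
                      color_range, rng: np.random.Generator) -> None:
    (r0, r1), (g0, g1), (b0, b1) = color_range
    base = np.array([rng.uniform(r0, r1), rng.uniform(g0, g1),
                     rng.uniform(b0, b1)])
    n = int(mask.sum())
    jitter = rng.normal(0, 4.0, size=(n, 3))
    vals = np.clip(base[None, :] + jitter, [r0, g0, b0], [r1, g1, b1])
    pixels[mask] = vals.astype(np.uint8)


def _box_gap(a: np.ndarray, b: np.ndarray) -> float:
    """Smallest axis-aligned gap between two (x1,y1,x2,y2) boxes; 0 if they touch."""
    dx = max(a[0] - b[2], b[0] - a[2], 0.0)
    dy = max(a[1] - b[3], b[1] - a[3], 0.0)
    return max(dx, dy) if (dx == 0 or dy == 0) else math.hypot(dx, dy)


def _corner_iou(a: np.ndarray, b: np.ndarray) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / ua if ua > 0 else 0.0


MAX_PLACEMENT_IOU = 0.05  # placed objects must not overlap beyond this


def generate_scene(params: SceneParams, image_id: str = "scene-0") -> AnnotatedImage:
    """Paint one field scene; deterministic given ``params.seed``.

    Raises :class:`PlacementError` when an object cannot be placed within
    ``params.max_attempts`` rejection-sampling attempts under the overlap and
    ``min_object_separation`` constraints.
    """
    rng = np.random.default_rng(params.seed)
    w, h = params.image_size
    pixels = np.empty((h, w, 3), dtype=np.uint8)
    soil = np.array(SOIL_RGB, dtype=float)
    noise = rng.normal(0.0, params.soil_texture_noise, size=(h, w, 3))
    pixels[:] = np.clip(soil[None, None, :] + noise, 0, 255).astype(np.uint8)

    placed: list[np.ndarray] = []   # corner boxes
    boxes: list[tuple[int, float, float, float, float]] = []
    masks: list[np.ndarray] = []

    specs = [(CROP, params.crop_radius_range)] * params.n_crops + \
            [(WEED, params.weed_radius_range)] * params.n_weeds
    for cls, (rmin, rmax) in specs:
        for _ in range(params.max_attempts):
            r = rng.uniform(rmin, rmax)
            margin = r * 1.4 + 1
            if 2 * margin >= min(w, h):
                raise PlacementError(
                    f"object radius {r:.1f} too large for image {w}x{h}")
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
            if cls == CROP:
                mask = _ellipse_mask((h, w), cx, cy, r * rng.uniform(0.85, 1.15),
                                     r * rng.uniform(0.85, 1.15),
                                     rng.uniform(0, math.pi))
            else:
                mask = _weed_mask((h, w), cx, cy, r, rng)
            ys, xs = np.nonzero(mask)
            corner = np.array([xs.min(), ys.min(), xs.max() + 1, ys.max() + 1],
                              dtype=float)
            if any(_corner_iou(corner, p) > MAX_PLACEMENT_IOU for p in placed):
                continue
            if any(_box_gap(corner, p) < params.min_object_separation
                   for p in placed):
                continue
            _paint_vegetation(pixels, mask, params.vegetation_color_range, rng)
            placed.append(corner)
            cxn, cyn, bw, bh = mask_to_normalized_box(mask)
            boxes.append((cls, cxn, cyn, bw, bh))
            masks.append(mask)
            break
        else:
            raise PlacementError(
                f"could not place a class-{cls} object after "
                f"{params.max_attempts} attempts under min_object_separation="
                f"{params.min_object_separation} and IoU<={MAX_PLACEMENT_IOU}")

    return AnnotatedImage(pixels=pixels, boxes=boxes, provenance="original",
                          image_id=image_id, object_masks=masks)


def _partition_counts(total: int, n_images: int, rng: np.random.Generator) -> np.ndarray:
    """Split ``total`` objects across images as evenly as possible; the images
    receiving the remainder are chosen at random (deterministic given rng)."""
    base, rem = divmod(total, n_images)
    counts = np.full(n_images, base, dtype=int)
    if rem:
        counts[rng.choice(n_images, size=rem, replace=False)] += 1
    return counts


def generate_corpus(
    n_images: int,
    params: SceneParams,
    class_ratio: tuple[int, int] = (17, 3),
    objects_per_image: int | None = None,
) -> tuple[list[AnnotatedImage], pd.DataFrame]:
    """Generate a corpus whose aggregate crop:weed counts match ``class_ratio``.

    The total object budget is ``n_images * objects_per_image`` (default: the
    per-scene counts in ``params``); the largest multiple of the reduced ratio
    that fits the budget is used, so e.g. 20 images at 10 objects each with
    ratio 17:3 yields exactly 170 crops and 30 weeds.

    Returns the images and a manifest DataFrame with columns
    ``id, path, provenance, source_id, split``.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    a, b = class_ratio
    if a < 0 or b < 0 or a + b == 0:
        raise ValueError("class_ratio must be non-negative and non-trivial")
    g = math.gcd(a, b) or 1
    a, b = a // g, b // g
    opi = objects_per_image if objects_per_image is not None \
        else params.n_crops + params.n_weeds
    k = (n_images * opi) // (a + b)
    if k < 1:
        raise ValueError(
            f"ratio {a}:{b} infeasible for {n_images} images of ~{opi} objects")
    total_crops, total_weeds = k * a, k * b

    rng = np.random.default_rng(params.seed)
    crop_counts = _partition_counts(total_crops, n_images, rng)
    weed_counts = _partition_counts(total_weeds, n_images, rng)
    scene_seeds = rng.integers(0, 2 ** 31 - 1, size=n_images)

    images, rows = [], []
    for i in range(n_images):
        image_id = f"img-{i:05d}"
        p = replace(params, n_crops=int(crop_counts[i]),
                    n_weeds=int(weed_counts[i]), seed=int(scene_seeds[i]))
        img = generate_scene(p, image_id=image_id)
        images.append(img)
        rows.append({"id": image_id, "path": "", "provenance": "original",
                     "source_id": "", "split": ""})
    manifest = pd.DataFrame(rows, columns=["id", "path", "provenance",
                                           "source_id", "split"])
    return images, manifest


# --------------------------------------------------------------------- I/O
def write_yolo_labels(path: str | Path, boxes) -> None:
    lines = [f"{int(c)} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"
             for c, cx, cy, w, h in boxes]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_labels(path: str | Path) -> list[tuple[int, float, float, float, float]]:
    boxes = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        boxes.append((int(parts[0]), *(float(v) for v in parts[1:5])))
    return boxes


def write_corpus(images: list[AnnotatedImage], manifest: pd.DataFrame,
                 outdir: str | Path) -> pd.DataFrame:
    """Write PNGs, YOLO label files and a tab-delimited manifest.

    Returns the manifest with its ``path`` column filled in.
    """
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "labels").mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    by_id = {img.image_id: img for img in images}
    for i, row in manifest.iterrows():
        img = by_id[row["id"]]
        rel = f"images/{img.image_id}.png"
        Image.fromarray(img.pixels).save(outdir / rel)
        write_yolo_labels(outdir / "labels" / f"{img.image_id}.txt", img.boxes)
        manifest.loc[i, "path"] = rel
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest


def read_corpus(root: str | Path) -> tuple[list[AnnotatedImage], pd.DataFrame]:
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.tsv", sep="\t",
                           keep_default_na=False)
    images = []
    for _, row in manifest.iterrows():
        pixels = np.asarray(Image.open(root / row["path"]).convert("RGB"))
        boxes = read_yolo_labels(root / "labels" / f"{row['id']}.txt")
        images.append(AnnotatedImage(pixels=pixels, boxes=boxes,
                                     provenance=row["provenance"],
                                     source_id=row["source_id"],
                                     image_id=row["id"]))
    return images, manifest


def excess_green(pixels: np.ndarray) -> np.ndarray:
    """Excess-green vegetation index 2G - R - B per pixel (float array)."""
    p = pixels.astype(np.int32)
    return (2 * p[..., 1] - p[..., 0] - p[..., 2]).astype(float)
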