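"""Pixel-level copy-paste augmentation for unbalanced weed/crop corpora.

The pipeline mirrors how a weed-scarce detection corpus is rebalanced in
practice: weed plants are segmented out of weed-only sub-images by region
growing, kept in a patch bank, and pasted at random positions into original
images, producing synthetic images with extra weed annotations.  Pasting
raises the weed object count without touching crop annotations, so a corpus
at crop:weed 17:3 pasted with two extra weeds per existing weed lands at
exactly 17:9.

Because a synthetic image shares plants with the original it was derived
from, the train/val/test split pins every synthetic image *and its source
original* to the training set; only the remaining originals are partitioned
toward the requested ratios.  This leakage rule is the part of the split that
is a hard contract — exact split sizes are not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import AffineTransform, warp

from .synthdata import (
    WEED,
    AnnotatedImage,
    excess_green,
    mask_to_normalized_box,
)


class RegionGrowthError(RuntimeError):
    pass


class PasteError(RuntimeError):
    pass


class SplitError(RuntimeError):
    pass


@dataclass
class RegionGrowConfig:
    """Region growing with a fixed criterion: a pixel joins the region when
    its Euclidean RGB distance to the *seed pixel's* color is at most
    ``color_distance_threshold``.  A fixed criterion (rather than a running
    region mean) makes the result independent of visiting order."""

    connectivity: int = 8
    color_distance_threshold: float = 60.0
    seed_strategy: str = "max_excess_green"   # or "manual"
    max_region_pixels: int | None = None

    def __post_init__(self):
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.color_distance_threshold < 0:
            raise ValueError("color_distance_threshold must be >= 0")
        if self.seed_strategy not in ("manual", "max_excess_green"):
            raise ValueError(f"unknown seed_strategy {self.seed_strategy!r}")


@dataclass
class WeedPatch:
    """An irregular set of weed pixels cut out of a source image."""

    pixels: np.ndarray            # (h, w, 3) uint8, valid under mask
    mask: np.ndarray              # (h, w) bool, single connected component
    bbox: tuple[int, int, int, int]   # (x1, y1, x2, y2) in source pixel coords
    origin_image: str = ""

    def __post_init__(self):
        if self.mask.sum() < 1:
            raise ValueError("weed patch mask must contain at least one pixel")
        ys, xs = np.nonzero(self.mask)
        if (ys.min() != 0 or xs.min() != 0
                or ys.max() != self.mask.shape[0] - 1
                or xs.max() != self.mask.shape[1] - 1):
            raise ValueError("patch bbox must be tight around the mask")


@dataclass
class PasteConfig:
    n_paste_per_image: int = 2
    max_overlap_iou: float = 0.05
    scale_jitter: tuple[float, float] = (1.0, 1.0)
    flip: bool = False
    seed: int = 0
    max_attempts: int = 100


@dataclass
class SplitSpec:
    ratios: tuple[float, float, float] = (8.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if min(self.ratios) < 0 or sum(self.ratios) <= 0:
            raise ValueError("split ratios must be non-negative with positive sum")


@dataclass
class ExtractionResult:
    patches: list[WeedPatch] = field(default_factory=list)
    failed_boxes: list[int] = field(default_factory=list)  # indices into subimage.boxes


# ----------------------------------------------------------- region growing
def region_grow(image: np.ndarray, seed_point: tuple[int, int],
                config: RegionGrowConfig) -> np.ndarray:
    """Grow a region from ``seed_point`` (row, col); returns a boolean mask.

    With the fixed seed-color criterion the grown region is exactly the
    connected component, under the configured connectivity, of the pixel set
    ``{p : ||rgb(p) - rgb(seed)|| <= threshold}`` that contains the seed; it
    is computed here by component labeling, which visits pixels in a
    different order than a breadth-first search but returns the same set.
    """
    r, c = seed_point
    h, w = image.shape[:2]
    if not (0 <= r < h and 0 <= c < w):
        raise RegionGrowthError(f"seed point {seed_point} outside image {h}x{w}")
    diff = image.astype(float) - image[r, c].astype(float)
    candidate = np.sqrt((diff ** 2).sum(axis=-1)) <= config.color_distance_threshold
    structure = ndimage.generate_binary_structure(2, 2 if config.connectivity == 8 else 1)
    labels, _ = ndimage.label(candidate, structure=structure)
    mask = labels == labels[r, c]
    if config.max_region_pixels is not None and mask.sum() > config.max_region_pixels:
        raise RegionGrowthError(
            f"region of {int(mask.sum())} pixels exceeds max_region_pixels="
            f"{config.max_region_pixels}")
    return mask


def _seed_for_box(image: np.ndarray, box_px: tuple[int, int, int, int]) -> tuple[int, int]:
    """Pixel of maximum excess-green inside a pixel-corner box."""
    x1, y1, x2, y2 = box_px
    exg = excess_green(image[y1:y2, x1:x2])
    r, c = np.unravel_index(int(exg.argmax()), exg.shape)
    return y1 + r, x1 + c


def extract_weed_patches(subimage: AnnotatedImage,
                         config: RegionGrowConfig) -> ExtractionResult:
    """Segment one weed patch per weed box of a weed-only sub-image.

    Region growing is confined to each box's pixel region, so a patch's mask
    can never leak outside its annotation.  Boxes whose segmentation comes
    out empty (or collides with ``max_region_pixels``) are reported in
    ``failed_boxes`` rather than silently dropped.
    """
    if any(cls != WEED for cls, *_ in subimage.boxes):
        raise ValueError("extract_weed_patches expects a weed-only sub-image")
    result = ExtractionResult()
    pxboxes = subimage.pixel_boxes()
    for idx, (_, x1, y1, x2, y2) in enumerate(pxboxes):
        x1, y1 = int(math.floor(x1)), int(math.floor(y1))
        x2, y2 = int(math.ceil(x2)), int(math.ceil(y2))
        sub = subimage.pixels[y1:y2, x1:x2]
        try:
            if config.seed_strategy == "max_excess_green":
                exg = excess_green(sub)
                seed = np.unravel_index(int(exg.argmax()), exg.shape)
            else:
                seed = ((y2 - y1) // 2, (x2 - x1) // 2)
            mask = region_grow(sub, seed, config)
        except RegionGrowthError:
            result.failed_boxes.append(idx)
            continue
        if not mask.any():
            result.failed_boxes.append(idx)
            continue
        ys, xs = np.nonzero(mask)
        my1, my2, mx1, mx2 = ys.min(), ys.max() + 1, xs.min(), xs.max() + 1
        result.patches.append(WeedPatch(
            pixels=sub[my1:my2, mx1:mx2].copy(),
            mask=mask[my1:my2, mx1:mx2].copy(),
            bbox=(x1 + mx1, y1 + my1, x1 + mx2, y1 + my2),
            origin_image=subimage.image_id,
        ))
    return result


def build_patch_bank(images: list[AnnotatedImage], config: RegionGrowConfig,
                     pad: int = 2) -> list[WeedPatch]:
    """Collect weed patches from every weed annotation of a corpus.

    Each weed box is cropped (with ``pad`` pixels of context) into a
    weed-only sub-image and run through :func:`extract_weed_patches`; boxes
    whose segmentation fails are skipped.
    """
    bank: list[WeedPatch] = []
    for img in images:
        h, w = img.pixels.shape[:2]
        for cls, x1, y1, x2, y2 in img.pixel_boxes():
            if int(cls) != WEED:
                continue
            cx1 = max(0, int(math.floor(x1)) - pad)
            cy1 = max(0, int(math.floor(y1)) - pad)
            cx2 = min(w, int(math.ceil(x2)) + pad)
            cy2 = min(h, int(math.ceil(y2)) + pad)
            cw, chh = cx2 - cx1, cy2 - cy1
            sub = AnnotatedImage(
                pixels=img.pixels[cy1:cy2, cx1:cx2],
                boxes=[(WEED, (x1 + x2) / 2 / cw - cx1 / cw,
                        (y1 + y2) / 2 / chh - cy1 / chh,
                        (x2 - x1) / cw, (y2 - y1) / chh)],
                provenance=img.provenance, source_id=img.source_id,
                image_id=img.image_id)
            res = extract_weed_patches(sub, config)
            bank.extend(res.patches)
    return bank


# ------------------------------------------------------------------ pasting
def _resize_patch(patch: WeedPatch, scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbour rescale of patch pixels+mask (keeps hard edges)."""
    h, w = patch.mask.shape
    nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
    ri = np.clip((np.arange(nh) + 0.5) * h / nh, 0, h - 1).astype(int)
    ci = np.clip((np.arange(nw) + 0.5) * w / nw, 0, w - 1).astype(int)
    return patch.pixels[ri][:, ci], patch.mask[ri][:, ci]


def _iou_corner(a, b) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / ua if ua > 0 else 0.0


def synthesize_image(base: AnnotatedImage, bank: list[WeedPatch],
                     config: PasteConfig,
                     image_id: str | None = None) -> AnnotatedImage:
    """Paste ``config.n_paste_per_image`` weed patches into ``base``.

    Pasted pixels replace the background only under each patch's mask; all
    original pixels outside pasted masks and all original annotations are
    preserved verbatim.  Deterministic given ``config.seed``.
    """
    if config.n_paste_per_image > 0 and not bank:
        raise ValueError("patch bank is empty but n_paste_per_image > 0")
    rng = np.random.default_rng(config.seed)
    pixels = base.pixels.copy()
    h, w = pixels.shape[:2]
    boxes = list(base.boxes)
    existing = [tuple(b[1:]) for b in base.pixel_boxes()]

    for _ in range(config.n_paste_per_image):
        placed = False
        for _attempt in range(config.max_attempts):
            patch = bank[int(rng.integers(len(bank)))]
            scale = float(rng.uniform(*config.scale_jitter))
            ppix, pmask = _resize_patch(patch, scale)
            if config.flip and rng.integers(2):
                ppix, pmask = ppix[:, ::-1], pmask[:, ::-1]
            ph, pw = pmask.shape
            if ph >= h or pw >= w:
                continue
            y0 = int(rng.integers(0, h - ph + 1))
            x0 = int(rng.integers(0, w - pw + 1))
            ys, xs = np.nonzero(pmask)
            corner = (x0 + xs.min(), y0 + ys.min(), x0 + xs.max() + 1,
                      y0 + ys.max() + 1)
            if any(_iou_corner(corner, e) > config.max_overlap_iou
                   for e in existing):
                continue
            region = pixels[y0:y0 + ph, x0:x0 + pw]
            region[pmask] = ppix[pmask]
            full_mask = np.zeros((h, w), dtype=bool)
            full_mask[y0:y0 + ph, x0:x0 + pw] = pmask
            boxes.append((WEED, *mask_to_normalized_box(full_mask)))
            existing.append(corner)
            placed = True
            break
        if not placed:
            raise PasteError(
                f"could not place a weed patch within max_overlap_iou="
                f"{config.max_overlap_iou} after {config.max_attempts} attempts")

    return AnnotatedImage(
        pixels=pixels, boxes=boxes, provenance="synthetic",
        source_id=base.image_id,
        image_id=image_id or f"{base.image_id}-syn",
    )


# ----------------------------------------------------------------- counting
def class_ratio(corpus: list[AnnotatedImage]) -> tuple[tuple[int, int] | None, float | None]:
    """Aggregate crop:weed ratio over a corpus.

    Returns ``((a, b), a/b)`` with (a, b) the reduced integer pair, or
    ``(None, None)`` when the corpus has no weed boxes (undefined ratio).
    """
    if not corpus:
        raise ValueError("corpus is empty")
    crops = sum(img.class_counts().get(0, 0) for img in corpus)
    weeds = sum(img.class_counts().get(1, 0) for img in corpus)
    if weeds == 0:
        return None, None
    g = math.gcd(crops, weeds)
    return (crops // g, weeds // g), crops / weeds


# ------------------------------------------------------------------ splitting
def split_dataset(manifest: pd.DataFrame, spec: SplitSpec) -> pd.DataFrame:
    """Assign train/val/test splits with the synthetic-leakage constraint.

    Every synthetic image and the original it was derived from go to train;
    the remaining originals are shuffled (deterministic given ``spec.seed``)
    and partitioned so val and test approach their requested ratios.
    """
    manifest = manifest.copy()
    ids = set(manifest["id"])
    synthetic = manifest["provenance"] == "synthetic"
    sources = set(manifest.loc[synthetic, "source_id"])
    if missing := (sources - ids):
        raise SplitError(f"synthetic source_id(s) not in manifest: {sorted(missing)[:5]}")
    forced_train = synthetic | manifest["id"].isin(sources)

    n_total = len(manifest)
    free_idx = manifest.index[~forced_train].to_numpy()
    r_train, r_val, r_test = spec.ratios
    r_sum = r_train + r_val + r_test
    n_val = round(n_total * r_val / r_sum)
    n_test = round(n_total * r_test / r_sum)
    if r_val > 0:
        n_val = max(n_val, 1)
    if r_test > 0:
        n_test = max(n_test, 1)
    if n_val + n_test > len(free_idx):
        raise SplitError(
            f"leakage constraint leaves only {len(free_idx)} free images but "
            f"val+test need {n_val + n_test}")

    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(free_idx))
    free = free_idx[order]
    split = pd.Series("train", index=manifest.index)
    split.loc[free[:n_val]] = "val"
    split.loc[free[n_val:n_val + n_test]] = "test"
    manifest["split"] = split
    return manifest


# ------------------------------------------------ conventional augmentation
def conventional_augment(
    image: AnnotatedImage,
    translation: tuple[float, float] = (0.0, 0.0),
    rotation_deg: tuple[float, float] = (0.0, 0.0),
    scaling: tuple[float, float] = (1.0, 1.0),
    seed: int = 0,
    min_box_area_px: float = 4.0,
    image_id: str | None = None,
) -> AnnotatedImage:
    """Random translate/rotate/scale baseline augmentation.

    The same affine map (about the image center) is applied to pixels and to
    box corners; boxes are re-tightened to the transformed corner hull,
    clipped to the image, and dropped when their clipped area falls below
    ``min_box_area_px``.
    """
    rng = np.random.default_rng(seed)
    h, w = image.pixels.shape[:2]
    dx = float(rng.uniform(translation[0], translation[1]))
    dy = float(rng.uniform(translation[0], translation[1]))
    ang = math.radians(float(rng.uniform(rotation_deg[0], rotation_deg[1])))
    sc = float(rng.uniform(scaling[0], scaling[1]))

    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    shift_to = AffineTransform(translation=-center)
    core = AffineTransform(rotation=ang, scale=(sc, sc))
    shift_back = AffineTransform(translation=center + np.array([dx, dy]))
    tform = shift_to + core + shift_back

    warped = warp(image.pixels, tform.inverse, order=1, mode="constant",
                  cval=0.0, preserve_range=True).astype(np.uint8)

    new_boxes = []
    for cls, cx, cy, bw, bh in image.boxes:
        x1, y1 = (cx - bw / 2) * w, (cy - bh / 2) * h
        x2, y2 = (cx + bw / 2) * w, (cy + bh / 2) * h
        corners = np.array([[x1, y1], [x2, y1], [x1, y2], [x2, y2]])
        tc = tform(corners)
        nx1, ny1 = tc.min(axis=0)
        nx2, ny2 = tc.max(axis=0)
        nx1, nx2 = np.clip([nx1, nx2], 0, w)
        ny1, ny2 = np.clip([ny1, ny2], 0, h)
        if (nx2 - nx1) * (ny2 - ny1) < min_box_area_px:
            continue
        new_boxes.append((cls, (nx1 + nx2) / 2 / w, (ny1 + ny2) / 2 / h,
                          (nx2 - nx1) / w, (ny2 - ny1) / h))
    return AnnotatedImage(
        pixels=warped, boxes=new_boxes, provenance=image.provenance,
        source_id=image.source_id,
        image_id=image_id or f"{image.image_id}-aug",
    )
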