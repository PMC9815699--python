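"""Copy-paste augmentation: region growing, patch extraction, pasting,
ratio accounting, leakage-safe splitting, conventional baseline."""

import numpy as np
import pandas as pd
import pytest

from weeddet.augment import (
    PasteConfig,
    RegionGrowConfig,
    RegionGrowthError,
    SplitError,
    SplitSpec,
    WeedPatch,
    build_patch_bank,
    class_ratio,
    conventional_augment,
    extract_weed_patches,
    region_grow,
    split_dataset,
    synthesize_image,
)
from weeddet.synthdata import (
    CROP,
    WEED,
    AnnotatedImage,
    SceneParams,
    generate_corpus,
    generate_scene,
)

from .oracles import bfs_region_grow


# ------------------------------------------------------------ region growing
class TestRegionGrow:
    def test_uniform_image_grows_everywhere(self):
        img = np.full((10, 12, 3), 100, dtype=np.uint8)
        mask = region_grow(img, (4, 4), RegionGrowConfig(
            color_distance_threshold=5.0))
        assert mask.all()

    def test_isolated_seed_stays_single_pixel(self):
        img = np.zeros((5, 5, 3), dtype=np.uint8)
        img[2, 2] = 255
        mask = region_grow(img, (2, 2), RegionGrowConfig(
            color_distance_threshold=10.0))
        assert mask.sum() == 1 and mask[2, 2]

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_two_blob_image_matches_bfs_oracle(self, connectivity):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        img[1:4, 1:4] = (0, 200, 0)      # blob A
        img[6:9, 6:9] = (0, 200, 0)      # blob B, disconnected
        cfg = RegionGrowConfig(connectivity=connectivity,
                               color_distance_threshold=30.0)
        mask = region_grow(img, (2, 2), cfg)
        oracle = bfs_region_grow(img, (2, 2), 30.0, connectivity)
        assert np.array_equal(mask, oracle)
        assert not mask[6:9, 6:9].any()   # blob B untouched

    def test_matches_bfs_oracle_on_real_scene(self, weed_subimage):
        exg_seed = np.unravel_index(
            int((2 * weed_subimage.pixels[..., 1].astype(int)
                 - weed_subimage.pixels[..., 0]
                 - weed_subimage.pixels[..., 2]).argmax()),
            weed_subimage.pixels.shape[:2])
        cfg = RegionGrowConfig(color_distance_threshold=60.0)
        mask = region_grow(weed_subimage.pixels, exg_seed, cfg)
        oracle = bfs_region_grow(weed_subimage.pixels, exg_seed, 60.0, 8)
        assert np.array_equal(mask, oracle)

    def test_seed_outside_image_raises(self):
        img = np.zeros((5, 5, 3), dtype=np.uint8)
        with pytest.raises(RegionGrowthError, match="outside"):
            region_grow(img, (9, 0), RegionGrowConfig())

    def test_region_size_bound_is_enforced(self):
        img = np.full((20, 20, 3), 50, dtype=np.uint8)
        cfg = RegionGrowConfig(color_distance_threshold=5.0,
                               max_region_pixels=10)
        with pytest.raises(RegionGrowthError, match="max_region_pixels"):
            region_grow(img, (0, 0), cfg)


# ------------------------------------------------------------- extraction
class TestExtraction:
    def test_six_weeds_give_six_patches(self, weed_subimage):
        res = extract_weed_patches(weed_subimage, RegionGrowConfig())
        assert len(res.patches) == 6
        assert res.failed_boxes == []
        for p in res.patches:
            assert p.origin_image == weed_subimage.image_id
            assert p.mask.any()

    def test_no_weeds_gives_empty_list(self):
        img = generate_scene(SceneParams(seed=3, n_crops=0, n_weeds=0))
        res = extract_weed_patches(img, RegionGrowConfig())
        assert res.patches == [] and res.failed_boxes == []

    def test_crop_boxes_are_rejected(self, field_scene):
        with pytest.raises(ValueError, match="weed-only"):
            extract_weed_patches(field_scene, RegionGrowConfig())

    def test_masks_match_per_box_bfs_oracle(self, weed_subimage):
        cfg = RegionGrowConfig(color_distance_threshold=60.0)
        res = extract_weed_patches(weed_subimage, cfg)
        h, w = weed_subimage.pixels.shape[:2]
        import math
        for patch, (_, x1, y1, x2, y2) in zip(res.patches,
                                              weed_subimage.pixel_boxes()):
            x1, y1 = int(math.floor(x1)), int(math.floor(y1))
            x2, y2 = int(math.ceil(x2)), int(math.ceil(y2))
            sub = weed_subimage.pixels[y1:y2, x1:x2]
            exg = (2 * sub[..., 1].astype(int) - sub[..., 0] - sub[..., 2])
            seed = np.unravel_index(int(exg.argmax()), exg.shape)
            oracle = bfs_region_grow(sub, seed, 60.0, 8)
            full = np.zeros_like(oracle)
            bx1, by1, bx2, by2 = patch.bbox
            full[by1 - y1:by2 - y1, bx1 - x1:bx2 - x1] = patch.mask
            assert np.array_equal(full, oracle)

    def test_failed_segmentation_is_reported(self):
        # a "weed" box over bare soil: nothing green to grow from
        pixels = np.full((20, 20, 3), (120, 80, 60), dtype=np.uint8)
        img = AnnotatedImage(pixels=pixels,
                             boxes=[(WEED, 0.5, 0.5, 0.3, 0.3)],
                             image_id="bare")
        cfg = RegionGrowConfig(color_distance_threshold=5.0,
                               max_region_pixels=3)
        res = extract_weed_patches(img, cfg)
        assert res.failed_boxes == [0]
        assert res.patches == []

    def test_patch_bbox_must_be_tight(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = True   # not touching the borders -> not tight
        with pytest.raises(ValueError, match="tight"):
            WeedPatch(pixels=np.zeros((4, 4, 3), dtype=np.uint8),
                      mask=mask, bbox=(0, 0, 4, 4))


# ---------------------------------------------------------------- pasting
class TestPaste:
    @pytest.fixture()
    def bank(self, weed_subimage):
        return extract_weed_patches(weed_subimage, RegionGrowConfig()).patches

    def test_zero_paste_is_identity(self, field_scene, bank):
        out = synthesize_image(field_scene, bank,
                               PasteConfig(n_paste_per_image=0, seed=1))
        assert np.array_equal(out.pixels, field_scene.pixels)
        assert out.boxes == field_scene.boxes
        assert out.provenance == "synthetic"
        assert out.source_id == field_scene.image_id

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_pasting_k_adds_exactly_k_weed_boxes(self, field_scene, bank, k):
        out = synthesize_image(field_scene, bank,
                               PasteConfig(n_paste_per_image=k, seed=2))
        assert out.class_counts()[WEED] == field_scene.class_counts()[WEED] + k
        assert out.class_counts()[CROP] == field_scene.class_counts()[CROP]

    def test_original_annotations_preserved_verbatim(self, field_scene, bank):
        out = synthesize_image(field_scene, bank,
                               PasteConfig(n_paste_per_image=3, seed=2))
        assert out.boxes[:len(field_scene.boxes)] == field_scene.boxes

    def test_pixels_outside_pasted_masks_unchanged(self, field_scene, bank):
        out = synthesize_image(field_scene, bank,
                               PasteConfig(n_paste_per_image=3, seed=2))
        changed = (out.pixels != field_scene.pixels).any(axis=-1)
        # every changed pixel lies inside one of the new weed boxes
        h, w = changed.shape
        inside = np.zeros_like(changed)
        for cls, cx, cy, bw, bh in out.boxes[len(field_scene.boxes):]:
            x1, x2 = int((cx - bw / 2) * w), int(np.ceil((cx + bw / 2) * w))
            y1, y2 = int((cy - bh / 2) * h), int(np.ceil((cy + bh / 2) * h))
            inside[y1:y2, x1:x2] = True
        assert not (changed & ~inside).any()

    def test_deterministic_given_seed(self, field_scene, bank):
        a = synthesize_image(field_scene, bank,
                             PasteConfig(n_paste_per_image=2, seed=9))
        b = synthesize_image(field_scene, bank,
                             PasteConfig(n_paste_per_image=2, seed=9))
        assert np.array_equal(a.pixels, b.pixels) and a.boxes == b.boxes

    def test_empty_bank_rejected(self, field_scene):
        with pytest.raises(ValueError, match="empty"):
            synthesize_image(field_scene, [],
                             PasteConfig(n_paste_per_image=1))


# ---------------------------------------------------------------- ratios
class TestClassRatio:
    def _corpus(self, crops, weeds):
        pixels = np.zeros((10, 10, 3), dtype=np.uint8)
        boxes = ([(CROP, 0.5, 0.5, 0.1, 0.1)] * crops
                 + [(WEED, 0.5, 0.5, 0.1, 0.1)] * weeds)
        return [AnnotatedImage(pixels=pixels, boxes=boxes, image_id="x")]

    @pytest.mark.parametrize("crops,weeds,expected", [
        (170, 30, (17, 3)),
        (5, 5, (1, 1)),
        (170, 90, (17, 9)),
    ])
    def test_reduced_ratio(self, crops, weeds, expected):
        pair, value = class_ratio(self._corpus(crops, weeds))
        assert pair == expected
        assert value == pytest.approx(crops / weeds)

    def test_zero_weeds_is_flagged_not_an_error(self):
        pair, value = class_ratio(self._corpus(5, 0))
        assert pair is None and value is None

    def test_pasting_strictly_decreases_ratio(self, field_scene,
                                              weed_subimage):
        bank = extract_weed_patches(weed_subimage,
                                    RegionGrowConfig()).patches
        _, before = class_ratio([field_scene])
        out = synthesize_image(field_scene, bank,
                               PasteConfig(n_paste_per_image=2, seed=4))
        _, after = class_ratio([out])
        assert after < before

    def test_seventeen_three_becomes_seventeen_nine(self, small_scene_params):
        """Pasting two weeds per existing weed rebalances 17:3 to 17:9."""
        images, _ = generate_corpus(10, small_scene_params, (17, 3),
                                    objects_per_image=10)
        sub = generate_scene(
            SceneParams(seed=11, n_crops=0, n_weeds=6), image_id="sub")
        bank = extract_weed_patches(sub, RegionGrowConfig()).patches
        pasted = []
        for i, img in enumerate(images):
            k = 2 * img.class_counts().get(WEED, 0)
            pasted.append(synthesize_image(
                img, bank, PasteConfig(n_paste_per_image=k, seed=100 + i),
                image_id=f"syn-{i}"))
        pair, _ = class_ratio(pasted)
        assert pair == (17, 9)


# --------------------------------------------------------------- splitting
def _manifest(n_orig, n_syn):
    rows = [{"id": f"o{i}", "path": "", "provenance": "original",
             "source_id": "", "split": ""} for i in range(n_orig)]
    rows += [{"id": f"s{i}", "path": "", "provenance": "synthetic",
              "source_id": f"o{i}", "split": ""} for i in range(n_syn)]
    return pd.DataFrame(rows)


class TestSplit:
    def test_unconstrained_8_1_1(self):
        out = split_dataset(_manifest(10, 0), SplitSpec((8, 1, 1), seed=0))
        assert out["split"].value_counts().to_dict() == {
            "train": 8, "val": 1, "test": 1}

    def test_synthetic_and_sources_confined_to_train(self):
        out = split_dataset(_manifest(40, 10), SplitSpec((8, 1, 1), seed=3))
        syn = out["provenance"] == "synthetic"
        sources = set(out.loc[syn, "source_id"])
        pinned = out[syn | out["id"].isin(sources)]
        assert (pinned["split"] == "train").all()
        assert len(out) == 50
        assert set(out["split"]) == {"train", "val", "test"}

    def test_leakage_invariant_over_seeds(self):
        m = _manifest(30, 8)
        for seed in range(20):
            out = split_dataset(m, SplitSpec((8, 1, 1), seed=seed))
            syn = out["provenance"] == "synthetic"
            sources = set(out.loc[syn, "source_id"])
            outside = out[(out["split"] != "train")
                          & (syn | out["id"].isin(sources))]
            assert outside.empty

    def test_deterministic_given_seed(self):
        m = _manifest(25, 5)
        a = split_dataset(m, SplitSpec((8, 1, 1), seed=11))
        b = split_dataset(m, SplitSpec((8, 1, 1), seed=11))
        assert a.equals(b)

    def test_infeasible_constraint_raises(self):
        # every original is a synthetic source -> nothing left for val/test
        out = _manifest(5, 5)
        with pytest.raises(SplitError, match="free images"):
            split_dataset(out, SplitSpec((8, 1, 1), seed=0))

    def test_unresolvable_source_raises(self):
        m = _manifest(5, 1)
        m.loc[m["provenance"] == "synthetic", "source_id"] = "ghost"
        with pytest.raises(SplitError, match="ghost"):
            split_dataset(m, SplitSpec())


# ------------------------------------------------ conventional augmentation
class TestConventional:
    def test_identity_ranges_leave_image_unchanged(self, field_scene):
        out = conventional_augment(field_scene, translation=(0, 0),
                                   rotation_deg=(0, 0), scaling=(1, 1))
        assert np.array_equal(out.pixels, field_scene.pixels)
        for a, b in zip(out.boxes, field_scene.boxes):
            np.testing.assert_allclose(a[1:], b[1:], atol=1e-6)

    def test_pure_translation_shifts_box_centers(self):
        # interior boxes only, so nothing is clipped at the border
        pixels = np.zeros((80, 100, 3), dtype=np.uint8)
        boxes = [(CROP, 0.4, 0.5, 0.2, 0.2), (WEED, 0.6, 0.35, 0.1, 0.1)]
        img = AnnotatedImage(pixels=pixels, boxes=boxes, image_id="t")
        d = 6.0
        out = conventional_augment(img, translation=(d, d))
        for (ca, xa, ya, wa, ha), (cb, xb, yb, wb, hb) in zip(
                boxes, out.boxes):
            np.testing.assert_allclose(xb - xa, d / 100, atol=1e-6)
            np.testing.assert_allclose(yb - ya, d / 80, atol=1e-6)
            np.testing.assert_allclose((wb, hb), (wa, ha), atol=1e-6)

    def test_double_half_turn_recovers_boxes(self, field_scene):
        once = conventional_augment(field_scene, rotation_deg=(180, 180))
        twice = conventional_augment(once, rotation_deg=(180, 180))
        w, h = field_scene.size
        assert len(twice.boxes) == len(field_scene.boxes)
        for a, b in zip(field_scene.boxes, twice.boxes):
            np.testing.assert_allclose(
                np.array(a[1:]) * [w, h, w, h],
                np.array(b[1:]) * [w, h, w, h], atol=1.0)


def test_patch_bank_collects_all_weed_boxes(small_corpus):
    images, _ = small_corpus
    bank = build_patch_bank(images, RegionGrowConfig())
    n_weeds = sum(i.class_counts().get(WEED, 0) for i in images)
    assert len(bank) == n_weeds
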