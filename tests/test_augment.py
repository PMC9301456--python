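"""Copy-paste augmentation: crop banks, filtering, placement, balancing."""

import numpy as np
import pytest

from pestdet.augment import (
    PastePolicy,
    balance_dataset,
    extract_instances,
    filter_crops,
    laplacian_sharpness,
    paste_instances,
    select_backgrounds,
)
from pestdet.boxes import BoundingBox, iou
from pestdet.voc import AnnotatedImage, AnnotatedObject, MAIZE_PEST_CLASSES


def _obj(cid, box, prov="original"):
    return AnnotatedObject(cid, MAIZE_PEST_CLASSES[cid], BoundingBox(*box), prov)


@pytest.fixture()
def flat_loader():
    """Loader returning a deterministic gradient image for any path."""

    def load(path):
        g = np.arange(100 * 120, dtype=np.uint8).reshape(100, 120) % 251
        return np.stack([g, g, g], axis=-1)

    return load


class TestExtract:
    def test_no_instances_gives_empty_bank(self, flat_loader):
        data = [AnnotatedImage("a.png", 120, 100, [_obj(5, (0, 0, 10, 10))])]
        assert extract_instances(data, 6, flat_loader) == []

    def test_crop_pixels_equal_source_region(self, scene_pool):
        img = scene_pool.images[0]
        cid = img.objects[0].class_id
        bank = extract_instances([img], cid, scene_pool.loader)
        crop = bank[0]
        b = crop.source_box
        src = scene_pool.pixels[img.image_path][b.ymin:b.ymax, b.xmin:b.xmax]
        assert np.array_equal(crop.pixels, src)

    def test_sticky_flag_matches_pairwise_iou(self, scene_pool):
        # brute-force: sticky iff its box overlaps any other GT in the image
        for img in scene_pool.images:
            for cid in img.class_ids():
                bank = extract_instances([img], cid, scene_pool.loader)
                wanted = [o for o in img.objects if o.class_id == cid]
                for crop, obj in zip(bank, wanted):
                    expect = any(
                        other is not obj and iou(obj.box, other.box) > 0
                        for other in img.objects
                    )
                    assert crop.sticky == expect

    def test_unreadable_image_skipped(self):
        def boom(path):
            raise OSError("no such image")

        data = [AnnotatedImage("a.png", 120, 100, [_obj(5, (0, 0, 10, 10))])]
        assert extract_instances(data, 5, boom) == []


class TestFilter:
    def _bank(self, scene_pool):
        img = scene_pool.images[0]
        cid = img.objects[0].class_id
        return extract_instances(scene_pool.images, cid, scene_pool.loader)

    def test_uniform_patch_has_zero_sharpness(self):
        assert laplacian_sharpness(np.full((8, 8, 3), 77, np.uint8)) == 0.0

    def test_identity_when_thresholds_off(self, scene_pool):
        bank = self._bank(scene_pool)
        assert filter_crops(bank, min_sharpness=0.0, exclude_sticky=False) == bank

    def test_threshold_counting(self, scene_pool):
        bank = self._bank(scene_pool)[:5]
        if len(bank) < 2:
            pytest.skip("bank too small for this scene draw")
        cut = sorted(c.sharpness for c in bank)[len(bank) // 2]
        kept = filter_crops(bank, min_sharpness=cut, exclude_sticky=False)
        assert len(kept) == sum(c.sharpness >= cut for c in bank)
        # order preserved
        assert kept == [c for c in bank if c.sharpness >= cut]

    def test_empty_bank_rejected(self):
        with pytest.raises(ValueError):
            filter_crops([], 0.0, False)


class TestBackgrounds:
    def test_count_filter_and_sorting(self):
        def img_with(n, name):
            objs = [_obj(5, (10 * i, 0, 10 * i + 5, 5)) for i in range(n)]
            return AnnotatedImage(name, 200, 50, objs)

        data = [img_with(7, "c.png"), img_with(1, "a.png"), img_with(3, "b.png")]
        out = select_backgrounds(data, 3)
        assert [i.image_path for i in out] == ["a.png", "b.png"]
        assert [len(i.objects) for i in out] == sorted(len(i.objects) for i in out)

    def test_max_zero_needs_object_free_images(self, scene_pool):
        # a collated dataset has no empty images, so nothing survives
        assert select_backgrounds(scene_pool.images, 0) == []


class TestPaste:
    def test_empty_crop_list_is_identity(self, scene_pool):
        img = scene_pool.images[0]
        res = paste_instances(scene_pool.pixels[img.image_path], img, [], PastePolicy(), 0)
        assert np.array_equal(res.pixels, scene_pool.pixels[img.image_path])
        assert res.image.objects == img.objects

    def test_zero_overlap_and_bookkeeping(self, scene_pool):
        img = scene_pool.images[0]
        cid = img.objects[0].class_id
        bank = extract_instances(scene_pool.images, cid, scene_pool.loader)[:4]
        res = paste_instances(
            scene_pool.pixels[img.image_path], img, bank, PastePolicy(), 11
        )
        boxes = [o.box for o in res.image.objects]
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                if i < len(img.objects) and j < len(img.objects):
                    continue  # pre-existing GT may already overlap
                assert iou(boxes[i], boxes[j]) == 0.0
        assert len(res.image.objects) == len(img.objects) + len(res.pasted)
        assert len(res.pasted) + len(res.skipped) == len(bank)
        m = PastePolicy().margin
        for obj in res.pasted:
            assert obj.provenance == "pasted"
            b = obj.box
            assert m <= b.xmin and b.xmax <= img.width - m
            assert m <= b.ymin and b.ymax <= img.height - m

    def test_seed_determinism(self, scene_pool):
        img = scene_pool.images[1]
        cid = img.objects[0].class_id
        bank = extract_instances(scene_pool.images, cid, scene_pool.loader)[:3]
        a = paste_instances(scene_pool.pixels[img.image_path], img, bank, PastePolicy(), 9)
        b = paste_instances(scene_pool.pixels[img.image_path], img, bank, PastePolicy(), 9)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.image.objects == b.image.objects

    def test_oversized_crop_errors(self, scene_pool):
        img = scene_pool.images[0]
        from pestdet.augment import InstanceCrop

        big = InstanceCrop(
            pixels=np.zeros((300, 300, 3), np.uint8),
            class_id=5, class_name="Armyworm", source_image="x.png",
            source_box=BoundingBox(0, 0, 300, 300), sharpness=1.0, sticky=False,
        )
        with pytest.raises(ValueError, match="cannot fit"):
            paste_instances(scene_pool.pixels[img.image_path], img, [big], PastePolicy(), 0)


class TestBalance:
    def _setup(self, scene_pool):
        counts = {}
        for im in scene_pool.images:
            for o in im.objects:
                counts[o.class_id] = counts.get(o.class_id, 0) + 1
        cid = min(counts, key=counts.get)
        bank = [
            c for c in extract_instances(scene_pool.images, cid, scene_pool.loader)
            if not c.sticky
        ]
        return cid, counts[cid], bank

    def test_targets_already_met_create_nothing(self, scene_pool):
        cid, current, bank = self._setup(scene_pool)
        report = balance_dataset(
            scene_pool.images, {cid: bank}, {cid: current}, PastePolicy(), 0,
            image_loader=scene_pool.loader,
        )
        assert report.new_images == [] and report.shortfall == {cid: 0}

    def test_deficit_reached_or_reported(self, scene_pool):
        cid, current, bank = self._setup(scene_pool)
        if not bank:
            pytest.skip("no clean crops for rarest class in this draw")
        target = current + 7
        report = balance_dataset(
            scene_pool.images, {cid: bank}, {cid: target}, PastePolicy(), 3,
            image_loader=scene_pool.loader,
        )
        # re-summarize: original + pasted instances of cid
        total = sum(
            o.class_id == cid for im in scene_pool.images for o in im.objects
        ) + sum(
            o.class_id == cid and o.provenance == "pasted"
            for _, im in report.new_images for o in im.objects
        )
        assert total == report.achieved[cid]
        assert report.achieved[cid] >= target or report.shortfall[cid] > 0

    def test_originals_untouched_and_determinism(self, scene_pool):
        cid, current, bank = self._setup(scene_pool)
        if not bank:
            pytest.skip("no clean crops for rarest class in this draw")
        args = (scene_pool.images, {cid: bank}, {cid: current + 4}, PastePolicy(), 8)
        r1 = balance_dataset(*args, image_loader=scene_pool.loader)
        r2 = balance_dataset(*args, image_loader=scene_pool.loader)
        assert [im.image_path for _, im in r1.new_images] == [
            im.image_path for _, im in r2.new_images
        ]
        for (p1, i1), (p2, i2) in zip(r1.new_images, r2.new_images):
            assert np.array_equal(p1, p2) and i1.objects == i2.objects
        # non-target classes unchanged in originals (they are never mutated)
        assert all(
            o.provenance == "original"
            for im in scene_pool.images for o in im.objects
        )

    def test_target_below_current_rejected(self, scene_pool):
        cid, current, bank = self._setup(scene_pool)
        with pytest.raises(ValueError):
            balance_dataset(
                scene_pool.images, {cid: bank}, {cid: max(0, current - 1)},
                PastePolicy(), 0, image_loader=scene_pool.loader,
            )
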