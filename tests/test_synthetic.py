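import json

import numpy as np
import pytest

from algadet.boxes import Box
from algadet.metrics import DetectionRecord, mean_ap
from algadet.synthetic import (
    CLASS_NAMES,
    SceneAnnotation,
    SceneSpec,
    YoloParseError,
    build_dataset,
    generate_scene,
    load_image,
    random_scale,
    read_yolo_labels,
    salt_pepper,
    save_image,
    write_yolo_labels,
)


class TestSceneGeneration:
    def test_deterministic_under_seed(self):
        spec = SceneSpec.easy(96, seed=4)
        a, b = generate_scene(spec), generate_scene(spec)
        assert np.array_equal(a.image, b.image)
        assert a.records == b.records

    def test_zero_instances(self):
        spec = SceneSpec(width=64, height=64, instances_per_image=(0, 0))
        scene = generate_scene(spec)
        assert scene.records == []
        assert scene.image.shape == (64, 64)

    def test_seven_default_classes(self):
        assert len(CLASS_NAMES) == 7
        assert len(SceneSpec().classes) == 7

    def test_boxes_are_tight_around_rendered_masks(self):
        spec = SceneSpec.easy(128, seed=9)
        scene = generate_scene(spec, keep_masks=True)
        assert len(scene.masks) == len(scene.records)
        h, w = scene.image.shape
        for (cid, box), mask in zip(scene.records, scene.masks):
            rows = np.flatnonzero(mask.any(axis=1))
            cols = np.flatnonzero(mask.any(axis=0))
            assert abs(box.w * w - (cols[-1] - cols[0] + 1)) <= 1
            assert abs(box.h * h - (rows[-1] - rows[0] + 1)) <= 1
            assert abs((box.cx - box.w / 2) * w - cols[0]) <= 1
            assert abs((box.cy - box.h / 2) * h - rows[0]) <= 1

    def test_all_boxes_normalized_and_inside(self):
        scene = generate_scene(SceneSpec(width=96, height=96, seed=2))
        for cid, b in scene.records:
            assert 0 <= b.cx - b.w / 2 and b.cx + b.w / 2 <= 1
            assert 0 <= b.cy - b.h / 2 and b.cy + b.h / 2 <= 1
            assert 0 <= cid < 7

    def test_single_species_scenes(self):
        scene = generate_scene(SceneSpec.easy(96, species=3, seed=1))
        assert scene.records and all(cid == 3 for cid, _ in scene.records)

    def test_ground_truth_self_evaluation_is_perfect(self):
        scene = generate_scene(SceneSpec.easy(128, seed=5))
        recs = [DetectionRecord("0", c, 1.0, b) for c, b in scene.records]
        res = mean_ap(recs, recs)
        assert res.precision == res.recall == res.map50 == res.map5095 == 1.0


class TestSaltPepper:
    def test_zero_fraction_is_identity(self, rng):
        img = rng.random((50, 50))
        assert np.array_equal(salt_pepper(img, 0.0, seed=1), img)

    def test_full_fraction_extremes_only(self, rng):
        img = rng.uniform(0.2, 0.8, (40, 40))
        noisy = salt_pepper(img, 1.0, seed=1)
        assert np.all((noisy == 0.0) | (noisy == 1.0))

    def test_exact_pixel_count(self, rng):
        img = rng.uniform(0.2, 0.8, (100, 100))
        noisy = salt_pepper(img, 0.05, seed=3)
        assert int((noisy != img).sum()) == 500
        changed = noisy[noisy != img]
        assert np.isin(changed, [0.0, 1.0]).all()
        assert abs((changed == 0.0).sum() - (changed == 1.0).sum()) <= 1

    def test_untouched_pixels_bit_identical(self, rng):
        img = rng.random((30, 30))
        noisy = salt_pepper(img, 0.1, seed=2)
        mask = noisy == img
        assert np.array_equal(noisy[mask], img[mask])

    def test_integer_images_use_dtype_extremes(self, rng):
        img = rng.integers(50, 200, (20, 20), dtype=np.uint8)
        noisy = salt_pepper(img, 1.0, seed=0)
        assert set(np.unique(noisy)) <= {0, 255}

    def test_invalid_fraction(self, rng):
        with pytest.raises(ValueError):
            salt_pepper(rng.random((4, 4)), 1.5)


class TestRandomScale:
    def test_unit_range_is_identity(self):
        scene = generate_scene(SceneSpec.easy(64, seed=0))
        scaled = random_scale(scene, (1.0, 1.0), seed=5)
        assert np.array_equal(scaled.image, scene.image)
        assert scaled.records == scene.records

    def test_whole_image_rescale_keeps_normalized_labels(self):
        scene = generate_scene(SceneSpec.easy(64, seed=3))
        scaled = random_scale(scene, (1.3, 1.3), seed=1, mode="resize")
        assert scaled.image.shape == (83, 83)
        assert scaled.records == scene.records

    def test_center_crop_drops_outside_boxes(self):
        # an instance near the corner leaves the crop window at scale 2
        img = np.full((100, 100), 0.9)
        records = [(0, Box(0.07, 0.07, 0.1, 0.1)), (1, Box(0.5, 0.5, 0.1, 0.1))]
        scene = SceneAnnotation(image=img, records=records)
        scaled = random_scale(scene, (2.0, 2.0), seed=0, mode="crop_pad")
        assert scaled.image.shape == (100, 100)
        kept_classes = [cid for cid, _ in scaled.records]
        assert kept_classes == [1]

    def test_invalid_bounds(self):
        scene = SceneAnnotation(image=np.zeros((8, 8)), records=[])
        with pytest.raises(ValueError):
            random_scale(scene, (0.0, 1.0))
        with pytest.raises(ValueError):
            random_scale(scene, (1.0, 1.0), mode="stretch")


class TestYoloIO:
    def test_empty_records_empty_file(self, tmp_path):
        path = tmp_path / "empty.txt"
        write_yolo_labels([], path)
        assert path.read_text() == ""
        assert read_yolo_labels(path) == []

    def test_round_trip_of_random_records(self, tmp_path, rng):
        records = []
        for _ in range(50):
            cx, cy = rng.uniform(0.2, 0.8, 2)
            w, h = rng.uniform(0.05, 0.2, 2)
            records.append((int(rng.integers(7)), Box(cx, cy, w, h)))
        path = tmp_path / "labels.txt"
        write_yolo_labels(records, path)
        back = read_yolo_labels(path)
        assert len(back) == 50
        for (cid, box), (cid2, box2) in zip(records, back):
            assert cid == cid2
            assert np.allclose(
                [box.cx, box.cy, box.w, box.h], [box2.cx, box2.cy, box2.w, box2.h],
                atol=1e-6,
            )

    def test_fixed_line_format(self, tmp_path):
        path = tmp_path / "one.txt"
        path.write_text("0 0.5 0.5 0.1 0.2\n")
        [(cid, box)] = read_yolo_labels(path)
        assert cid == 0
        assert (box.cx, box.cy, box.w, box.h) == (0.5, 0.5, 0.1, 0.2)

    def test_score_column_round_trip(self, tmp_path):
        path = tmp_path / "pred.txt"
        write_yolo_labels([(2, Box(0.5, 0.5, 0.1, 0.1), 0.75)], path)
        [(cid, box, score)] = read_yolo_labels(path, with_scores=True)
        assert cid == 2 and score == pytest.approx(0.75)

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0 0.5 0.5 0.1 0.2\n1 0.5 oops 0.1 0.2\n")
        with pytest.raises(YoloParseError, match=":2"):
            read_yolo_labels(path)

    def test_wrong_field_count(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0 0.5 0.5\n")
        with pytest.raises(YoloParseError, match="5 or 6 fields"):
            read_yolo_labels(path)

    def test_png_round_trip(self, tmp_path, rng):
        img = rng.random((32, 32))
        save_image(img, tmp_path / "img.png")
        back = load_image(tmp_path / "img.png")
        assert back.shape == (32, 32)
        assert np.abs(back - img).max() <= 1 / 255 + 1e-9


class TestBuildDataset:
    def test_split_sizes_and_balance(self, easy_dataset):
        manifest = json.loads((easy_dataset / "manifest.json").read_text())
        counts = {k: len(v) for k, v in manifest["splits"].items()}
        assert counts == {"train": 56, "val": 7, "test": 7}
        for split in ("train", "val", "test"):
            per_class = [e["class_id"] for e in manifest["splits"][split]]
            assert sorted(set(per_class)) == list(range(7))

    def test_reproducible_hashes(self, tmp_path):
        spec = SceneSpec.easy(64)
        m1 = build_dataset(spec, 14, tmp_path / "a", seed=9)
        m2 = build_dataset(spec, 14, tmp_path / "b", seed=9)
        h1 = [(e["sha256_image"], e["sha256_label"]) for s in m1["splits"].values() for e in s]
        h2 = [(e["sha256_image"], e["sha256_label"]) for s in m2["splits"].values() for e in s]
        assert h1 == h2

    def test_different_seed_changes_content(self, tmp_path):
        spec = SceneSpec.easy(64)
        m1 = build_dataset(spec, 14, tmp_path / "a", seed=1)
        m2 = build_dataset(spec, 14, tmp_path / "b", seed=2)
        assert m1["splits"]["train"][0]["sha256_image"] != m2["splits"]["train"][0]["sha256_image"]

    def test_uneven_count_nearest_balance(self, tmp_path):
        with pytest.warns(UserWarning, match="balanced"):
            manifest = build_dataset(SceneSpec.easy(64), 16, tmp_path / "c", seed=0)
        total = sum(len(v) for v in manifest["splits"].values())
        assert total == 16

    def test_invalid_split_ratios(self, tmp_path):
        with pytest.raises(ValueError):
            build_dataset(SceneSpec.easy(64), 7, tmp_path / "d", split=(0.5, 0.2, 0.2))

    def test_labels_on_disk_parse_and_validate(self, easy_dataset):
        labels = sorted((easy_dataset / "labels" / "test").glob("*.txt"))
        assert labels
        for lbl in labels:
            for cid, box in read_yolo_labels(lbl):
                assert 0 <= cid < 7
                assert box.w > 0 and box.h > 0
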