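"""Data pipeline: label I/O, letterboxing, splitting, augmentation and
label analytics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fracdet.data import (AugmentConfig, BoxLabel, FormatError, hflip,
                          label_stats, letterbox, mosaic_and_affine,
                          preprocess, read_yolo_labels, split_dataset,
                          to_grayscale, write_yolo_labels)


def random_labels(rng, n):
    out = []
    for _ in range(n):
        w, h = rng.uniform(0.05, 0.4, 2)
        cx = rng.uniform(w / 2, 1 - w / 2)
        cy = rng.uniform(h / 2, 1 - h / 2)
        out.append(BoxLabel(int(rng.integers(0, 3)), cx, cy, w, h))
    return out


class TestLabelIO:
    def test_parse_single_line(self, tmp_path):
        p = tmp_path / "l.txt"
        p.write_text("1 0.5 0.5 0.2 0.3\n")
        (lab,) = read_yolo_labels(p)
        assert lab == BoxLabel(1, 0.5, 0.5, 0.2, 0.3)

    def test_roundtrip_many_random_labels(self, tmp_path, rng):
        labels = random_labels(rng, 100)
        p = tmp_path / "many.txt"
        write_yolo_labels(labels, p)
        back = read_yolo_labels(p)
        for a, b in zip(labels, back):
            assert a.class_id == b.class_id
            np.testing.assert_allclose([a.cx, a.cy, a.w, a.h],
                                       [b.cx, b.cy, b.w, b.h], atol=1e-6)

    def test_out_of_range_class_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 0.5 0.5 0.2 0.2\n3 0.5 0.5 0.2 0.3\n")
        with pytest.raises(FormatError, match=":2:"):
            read_yolo_labels(p)

    def test_coordinate_outside_unit_square_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("1 1.5 0.5 0.2 0.3\n")
        with pytest.raises(FormatError):
            read_yolo_labels(p)

    def test_wrong_field_count_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("1 0.5 0.5 0.2\n")
        with pytest.raises(FormatError, match="5 fields"):
            read_yolo_labels(p)


class TestPreprocess:
    def test_gray_input_preserved_up_to_scaling(self, rng):
        img = rng.integers(0, 255, (640, 640), dtype=np.uint8)
        chw, params = preprocess(img, 640)
        assert params.scale == 1.0 and params.pad_x == 0 and params.pad_y == 0
        np.testing.assert_allclose(chw[0], img / 255.0, atol=1e-6)
        np.testing.assert_array_equal(chw[0], chw[1])  # replicated channels

    def test_letterbox_arithmetic_for_wide_image(self):
        img = np.zeros((640, 1280, 3), dtype=np.uint8)
        out, params = letterbox(img, 640)
        assert out.shape == (640, 640, 3)
        assert params.scale == 0.5
        assert params.pad_y == 160 and params.pad_x == 0

    def test_box_mapping_roundtrip(self, rng):
        _, params = letterbox(np.zeros((480, 704, 3), np.float32), 640)
        for _ in range(100):
            x1, y1 = rng.uniform(0, 300, 2)
            x2, y2 = x1 + rng.uniform(1, 100), y1 + rng.uniform(1, 100)
            fwd = params.forward_box(x1, y1, x2, y2)
            back = params.backward_box(*fwd)
            np.testing.assert_allclose(back, [x1, y1, x2, y2], atol=1e-9)

    def test_luminance_weights(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[..., 0] = 100  # pure red
        gray = to_grayscale(img)
        np.testing.assert_allclose(gray[..., 0], 29.9, atol=1e-4)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            letterbox(np.zeros((0, 10, 3)), 640)


class TestSplit:
    def test_study_split_sizes(self):
        train, test = split_dataset(range(976), 0.8, seed=1)
        assert (len(train), len(test)) == (780, 196)

    def test_flip_doubled_seventy_thirty_split(self):
        train, val = split_dataset(range(1952), 0.7, seed=1)
        assert (len(train), len(val)) == (1366, 586)

    def test_same_seed_same_partition(self):
        a = split_dataset(range(100), 0.8, seed=5)
        b = split_dataset(range(100), 0.8, seed=5)
        assert a == b

    @given(n=st.integers(2, 400), seed=st.integers(0, 2**31 - 1),
           frac=st.floats(0.05, 0.95))
    @settings(max_examples=60, deadline=None)
    def test_partition_property(self, n, seed, frac):
        train, test = split_dataset(range(n), frac, seed=seed)
        assert len(train) == int(np.floor(frac * n))
        assert sorted(train + test) == list(range(n))
        assert not set(train) & set(test)

    def test_stratified_split_preserves_class_shares(self, rng):
        classes = np.repeat([0, 1, 2], [40, 100, 20])
        train, _ = split_dataset(list(range(160)), 0.8, seed=0,
                                 stratify_classes=classes)
        train_classes = classes[np.asarray(train)]
        assert np.bincount(train_classes).tolist() == [32, 80, 16]

    def test_too_few_ids_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1], 0.8, seed=0)


class TestHflip:
    def test_center_x_mirrors(self, rng):
        img = rng.random((8, 8))
        _, labels = hflip(img, [BoxLabel(0, 0.3, 0.4, 0.1, 0.1)])
        assert labels[0].cx == pytest.approx(0.7)
        assert labels[0].cy == pytest.approx(0.4)

    def test_involution(self, rng):
        img = rng.random((8, 10))
        labels = random_labels(rng, 5)
        img2, labels2 = hflip(*hflip(img, labels))
        np.testing.assert_array_equal(img, img2)
        for a, b in zip(labels, labels2):
            assert a.cx == pytest.approx(b.cx)

    def test_midline_fixed_point(self):
        _, labels = hflip(np.zeros((4, 4)), [BoxLabel(1, 0.5, 0.5, 0.2, 0.2)])
        assert labels[0].cx == pytest.approx(0.5)

    def test_flip_doubling_doubles_per_class_counts(self, rng):
        labels = random_labels(rng, 30)
        _, flipped = hflip(np.zeros((8, 8)), labels)
        combined = labels + flipped
        base = np.bincount([l.class_id for l in labels], minlength=3)
        doubled = np.bincount([l.class_id for l in combined], minlength=3)
        assert (doubled == 2 * base).all()


class TestMosaic:
    def _sources(self, rng, imgsz=64):
        imgs = [rng.integers(0, 255, (imgsz, imgsz)).astype(np.float32) for _ in range(4)]
        labs = [random_labels(rng, 2) for _ in range(4)]
        return imgs, labs

    def test_fixed_rng_gives_byte_identical_output(self, rng):
        imgs, labs = self._sources(rng)
        cfg = AugmentConfig()
        out1, l1 = mosaic_and_affine(imgs, labs, cfg, np.random.default_rng(3), imgsz=64)
        out2, l2 = mosaic_and_affine(imgs, labs, cfg, np.random.default_rng(3), imgsz=64)
        np.testing.assert_array_equal(out1, out2)
        assert [(l.class_id, l.cx, l.cy, l.w, l.h) for l in l1] == \
               [(l.class_id, l.cx, l.cy, l.w, l.h) for l in l2]

    def test_output_labels_always_valid(self, rng):
        cfg = AugmentConfig()
        for trial in range(10):
            imgs, labs = self._sources(rng)
            _, out = mosaic_and_affine(imgs, labs, cfg, np.random.default_rng(trial), imgsz=64)
            for l in out:  # BoxLabel construction itself validates ranges
                assert 0 < l.w <= 1 and 0 < l.h <= 1

    def test_extreme_translation_drops_all_boxes(self, rng):
        imgs, labs = self._sources(rng)
        cfg = AugmentConfig(translate=3.0, scale=0.0)  # shift canvas far away
        rng_shift = np.random.default_rng(0)

        class Forced:
            def uniform(self, lo, hi, *a):
                return hi if hi > 1 else rng_shift.uniform(lo, hi, *a)

            def __getattr__(self, name):
                return getattr(rng_shift, name)

        _, out = mosaic_and_affine(imgs, labs, cfg, Forced(), imgsz=64)
        assert out == []

    def test_wrong_source_count_rejected(self, rng):
        imgs, labs = self._sources(rng)
        with pytest.raises(ValueError):
            mosaic_and_affine(imgs[:3], labs[:3], AugmentConfig(), rng)

    def test_probabilities_validated(self):
        with pytest.raises(ValueError):
            AugmentConfig(fliplr=1.5)


class TestLabelStats:
    def test_per_class_counts(self, rng):
        labels = []
        for cls, n in [(0, 261), (1, 579), (2, 136)]:
            labels += [BoxLabel(cls, 0.5, 0.5, 0.2, 0.2)] * n
        stats = label_stats(labels)
        assert stats["per_class_counts"] == [261, 579, 136]

    def test_degenerate_distribution_flagged(self):
        stats = label_stats([BoxLabel(0, 0.5, 0.5, 0.2, 0.2)] * 5)
        assert stats["correlations_degenerate"]
        assert np.allclose(stats["correlations"], 0)

    def test_constructed_perfect_correlation(self):
        labels = [BoxLabel(0, v, 0.5, v, 0.1) for v in (0.2, 0.3, 0.4)]
        stats = label_stats(labels)
        corr = np.asarray(stats["correlations"])
        assert corr[0, 2] == pytest.approx(1.0)  # cx vs w identical by construction

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            label_stats([])
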