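"""Segmentation network, augmentation and IoU evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from surgskill import segmentation as seg
from surgskill import synthdata


class TestBuild:
    def test_default_config_output_shape(self, scene_pair):
        img, _ = scene_pair
        model = seg.build_segmenter()
        out = model.forward_graph(img[None])
        assert out.shape == (1, 8, 64, 64)

    def test_initial_parameters_deterministic(self):
        a = seg.build_segmenter(seg.SegModelConfig(seed=4))
        b = seg.build_segmenter(seg.SegModelConfig(seed=4))
        assert all(np.array_equal(x, y)
                   for x, y in zip(a.state_arrays(), b.state_arrays()))

    def test_parameter_count_increases_with_width(self):
        p8 = seg.build_segmenter(seg.SegModelConfig(base_channels=8))
        p16 = seg.build_segmenter(seg.SegModelConfig(base_channels=16))
        assert p16.n_parameters() > p8.n_parameters()

    def test_incompatible_dims_instruct_padding(self):
        model = seg.build_segmenter()
        with pytest.raises(ValueError, match="pad"):
            model.forward_graph(np.zeros((1, 50, 64, 3)))


class TestIoU:
    def test_identity_is_one(self, scene_pair):
        _, mask = scene_pair
        per, mean = seg.iou(mask, mask)
        assert mean == 1.0
        assert all(v == 1.0 for v in per.values())

    def test_disjoint_regions_are_zero(self):
        a = np.zeros((8, 8), int)
        b = np.zeros((8, 8), int)
        a[0, 0] = 3
        b[7, 7] = 3
        per, _ = seg.iou(a, b)
        assert per[3] == 0.0

    def test_hand_counted_rectangle_overlap(self):
        """Two 2x3 same-class rectangles overlapping in 2 pixels:
        intersection 2, union 10, IoU 0.2."""
        a = np.zeros((6, 8), int)
        b = np.zeros((6, 8), int)
        a[0:2, 0:3] = 5   # rows 0-1, cols 0-2
        b[1:3, 1:4] = 5   # rows 1-2, cols 1-3; intersection = {(1,1),(1,2)}
        per, _ = seg.iou(a, b)
        assert per[5] == pytest.approx(2 / 10)

    def test_absent_classes_excluded_from_mean(self):
        a = np.zeros((4, 4), int)
        per, mean = seg.iou(a, a)
        assert list(per) == [0]
        assert mean == 1.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            seg.iou(np.zeros((4, 4), int), np.zeros((5, 5), int))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 8, size=(9, 9))
        b = rng.integers(0, 8, size=(9, 9))
        pa, ma = seg.iou(a, b)
        pb, mb = seg.iou(b, a)
        assert ma == pytest.approx(mb)
        assert pa == pb
        assert 0.0 <= ma <= 1.0


class TestAugment:
    def test_identity_ranges_return_input(self, scene_pair):
        img, mask = scene_pair
        p = seg.AugmentParams((1.0, 1.0), (0.0, 0.0), (0.0, 0.0))
        f, m = seg.augment_pair(img, mask, p, seed=0)
        assert np.allclose(f, img, atol=1e-8)
        assert np.array_equal(m, mask)

    def test_labels_stay_within_input_label_set(self, scene_pair):
        img, mask = scene_pair
        rng = np.random.default_rng(0)
        for _ in range(5):
            _, m = seg.augment_pair(img, mask, seed=rng)
            assert set(np.unique(m)) <= set(np.unique(mask)) | {0}

    def test_quarter_turn_moves_single_pixel_class(self):
        """A one-pixel class at (5, 10) in a 32x32 image rotated by 90
        degrees about the centre lands at (10, 26)."""
        mask = np.zeros((32, 32), np.uint8)
        mask[5, 10] = 3
        frame = np.zeros((32, 32, 3))
        p = seg.AugmentParams((1.0, 1.0), (90.0, 90.0), (0.0, 0.0))
        _, m = seg.augment_pair(frame, mask, p, seed=0)
        assert m[10, 26] == 3
        assert (m == 3).sum() == 1

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            seg.augment_pair(np.zeros((4, 4, 3)), np.zeros((5, 5), int))


class TestTrainPredict:
    def test_overfits_single_example(self, scene_pair):
        img, mask = scene_pair
        params = seg.SegTrainParams(steps=250, batch_size=1, augment=None,
                                    seed=0)
        model, curve = seg.train_segmenter([(img, mask)], params=params)
        train_points = [c for c in curve if c[1] == "train"]
        assert len(train_points) == 250  # one log row per optimizer step
        assert train_points[-1][2] > 0.9

    def test_prediction_shape_and_determinism(self, scene_pair):
        img, _ = scene_pair
        model = seg.build_segmenter()
        m1 = seg.predict_mask(model, img)
        m2 = seg.predict_mask(model, img)
        assert m1.shape == img.shape[:2]
        assert np.array_equal(m1, m2)
        assert set(np.unique(m1)) <= set(range(8))

    def test_empty_dataset_rejected_and_background_warns(self):
        with pytest.raises(ValueError):
            seg.train_segmenter([])
        neg = synthdata.generate_scene(
            synthdata.SceneSpec(parts_present=frozenset(), seed=0))
        with pytest.warns(UserWarning, match="no positive"):
            seg.train_segmenter([neg], params=seg.SegTrainParams(steps=1,
                                                                 seed=0))

    def test_checkpoint_roundtrip(self, tmp_path, scene_pair):
        img, _ = scene_pair
        model = seg.build_segmenter(seg.SegModelConfig(seed=8))
        path = tmp_path / "seg.npz"
        seg.save_checkpoint(model, path)
        back = seg.load_checkpoint(path)
        assert np.array_equal(seg.predict_mask(model, img),
                              seg.predict_mask(back, img))
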