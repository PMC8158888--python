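import itertools

import numpy as np
import pytest

from pancseg.cascade import (
    BoundingBox,
    EmptyMaskError,
    ViewPredictions,
    coarse_bbox,
    crop,
    fuse_views,
    predict_volume,
    run_pipeline,
    stitch,
)
from pancseg.synthetic import PhantomSpec, generate_phantom
from pancseg.volume_io import Volume


def _views(s, a, c):
    return ViewPredictions(
        sagittal=Volume(data=s.astype(float)),
        axial=Volume(data=a.astype(float)),
        coronal=Volume(data=c.astype(float)),
    )


class TestFuseViews:
    def test_all_eight_vote_patterns_match_majority_oracle(self):
        """Exhaustive per-voxel check of the 2-of-3 majority rule."""
        patterns = np.array(list(itertools.product([0, 1], repeat=3)))  # (8, 3)
        s = patterns[:, 0].reshape(8, 1, 1)
        a = patterns[:, 1].reshape(8, 1, 1)
        c = patterns[:, 2].reshape(8, 1, 1)
        fused = fuse_views(_views(s, a, c))
        expected = (patterns.sum(axis=1) >= 2).astype(np.uint8).reshape(8, 1, 1)
        np.testing.assert_array_equal(fused.data, expected)

    def test_probabilities_binarized_before_vote(self):
        # 0.6 and 0.4 must count as votes 1 and 0, not be averaged raw
        s = np.full((2, 1, 1), 0.6)
        a = np.full((2, 1, 1), 0.6)
        c = np.full((2, 1, 1), 0.4)
        fused = fuse_views(_views(s, a, c))
        np.testing.assert_array_equal(fused.data, 1)

    def test_permutation_invariance(self, rng):
        vols = [rng.random((4, 4, 4)) for _ in range(3)]
        results = [
            fuse_views(_views(*perm)).data for perm in itertools.permutations(vols)
        ]
        for r in results[1:]:
            np.testing.assert_array_equal(r, results[0])

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="shape"):
            _views(rng.random((4, 4, 4)), rng.random((4, 4, 4)), rng.random((4, 4, 5)))


class TestBoundingBox:
    def test_single_voxel_with_margin(self):
        mask = np.zeros((100, 100, 100), dtype=np.uint8)
        mask[10, 20, 30] = 1
        box = coarse_bbox(Volume(data=mask, is_mask=True), margin=5)
        assert box.lo == (5, 15, 25)
        assert box.hi == (16, 26, 36)
        assert box.shape == (11, 11, 11)

    def test_clipping_at_origin(self):
        mask = np.zeros((20, 20, 20), dtype=np.uint8)
        mask[0, 0, 0] = 1
        box = coarse_bbox(Volume(data=mask, is_mask=True), margin=5)
        assert box.lo == (0, 0, 0)
        assert box.hi == (6, 6, 6)

    def test_empty_mask_raises(self):
        empty = Volume(data=np.zeros((8, 8, 8), dtype=np.uint8), is_mask=True)
        with pytest.raises(EmptyMaskError, match="whole volume"):
            coarse_bbox(empty, margin=5)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            BoundingBox(lo=(5, 5, 5), hi=(5, 8, 8))


class TestCropStitch:
    def test_crop_shape_and_values(self, rng):
        v = Volume(data=rng.normal(size=(20, 20, 20)))
        box = BoundingBox(lo=(2, 3, 4), hi=(10, 13, 9))
        out = crop(v, box)
        assert out.shape == (8, 10, 5)
        np.testing.assert_array_equal(out.data, v.data[2:10, 3:13, 4:9])

    def test_full_volume_box_is_identity(self, rng):
        v = Volume(data=rng.normal(size=(6, 7, 8)))
        out = crop(v, BoundingBox(lo=(0, 0, 0), hi=(6, 7, 8)))
        np.testing.assert_array_equal(out.data, v.data)

    def test_out_of_bounds_rejected(self, rng):
        v = Volume(data=rng.normal(size=(6, 6, 6)))
        with pytest.raises(ValueError, match="bounds"):
            crop(v, BoundingBox(lo=(0, 0, 0), hi=(7, 6, 6)))

    def test_stitch_conserves_foreground(self, rng):
        box = BoundingBox(lo=(2, 2, 2), hi=(6, 7, 5))
        fine = Volume(
            data=(rng.random(box.shape) > 0.5).astype(np.uint8), is_mask=True
        )
        full = stitch(fine, box, (10, 10, 10))
        assert full.shape == (10, 10, 10)
        assert full.data.sum() == fine.data.sum()
        np.testing.assert_array_equal(full.data[box.slices()], fine.data)
        outside = full.data.copy()
        outside[box.slices()] = 0
        assert outside.sum() == 0

    def test_stitch_shape_mismatch(self):
        box = BoundingBox(lo=(0, 0, 0), hi=(4, 4, 4))
        with pytest.raises(ValueError, match="shape"):
            stitch(Volume(data=np.ones((3, 4, 4), dtype=np.uint8), is_mask=True), box, (8, 8, 8))

    def test_frame_contains_original_intensities(self, rng):
        """The safety frame around the tight box carries image values."""
        img = Volume(data=rng.normal(size=(30, 30, 30)))
        mask = np.zeros((30, 30, 30), dtype=np.uint8)
        mask[12:18, 12:18, 12:18] = 1
        box = coarse_bbox(Volume(data=mask, is_mask=True), margin=4)
        block = crop(img, box)
        # frame voxel (outside the tight bbox, inside the framed box)
        np.testing.assert_array_equal(block.data[0, 0, 0], img.data[8, 8, 8])


class TestRunPipeline:
    def test_oracle_models_reproduce_ground_truth(self, oracle_model_cls):
        image, gt = generate_phantom(PhantomSpec(shape=(32, 32, 24), seed=5))
        oracle = oracle_model_cls(image, gt)
        models = {ax: oracle for ax in ("sagittal", "coronal", "axial")}
        out = run_pipeline(image, models, models, margin=4)
        assert out.is_mask
        np.testing.assert_array_equal(out.data, gt.data)

    def test_output_binary_and_shape_matched(self, oracle_model_cls):
        image, gt = generate_phantom(PhantomSpec(shape=(32, 32, 24), seed=6))
        oracle = oracle_model_cls(image, gt)
        models = {ax: oracle for ax in ("sagittal", "coronal", "axial")}
        out = run_pipeline(image, models, models, margin=4)
        assert out.shape == image.shape
        assert set(np.unique(out.data)) <= {0, 1}

    def test_foreground_confined_to_box(self, oracle_model_cls):
        image, gt = generate_phantom(PhantomSpec(shape=(32, 32, 24), seed=7))
        oracle = oracle_model_cls(image, gt)
        models = {ax: oracle for ax in ("sagittal", "coronal", "axial")}
        out, coarse_mask = run_pipeline(image, models, models, margin=3, return_coarse=True)
        box = coarse_bbox(coarse_mask, margin=3)
        outside = out.data.copy()
        outside[box.slices()] = 0
        assert outside.sum() == 0

    def test_empty_coarse_falls_back_to_whole_volume(self, oracle_model_cls, caplog):
        image, gt = generate_phantom(PhantomSpec(shape=(32, 32, 24), seed=8))

        class EmptyCoarse:
            def predict_volume(self, v, axis):
                return Volume(data=np.zeros(v.shape))

        fine = {ax: oracle_model_cls(image, gt) for ax in ("sagittal", "coronal", "axial")}
        coarse = {ax: EmptyCoarse() for ax in ("sagittal", "coronal", "axial")}
        import logging

        with caplog.at_level(logging.WARNING, logger="pancseg.cascade"):
            out = run_pipeline(image, coarse, fine, margin=4)
        assert "empty coarse mask" in caplog.text
        np.testing.assert_array_equal(out.data, gt.data)


class TestPredictVolume:
    def test_trained_model_path_shapes(self, rng):
        """predict_volume slices, resizes, predicts and restacks at the
        native shape for every view."""
        from pancseg.network import ModelConfig, build_model

        m = build_model(
            ModelConfig(in_size=(16, 16), n_blocks=2, base_channels=2,
                        dense_layers=1, n3d_blocks=1),
            seed=0,
        )
        v = Volume(data=rng.random((12, 14, 10)) * 255)
        for axis in ("sagittal", "coronal", "axial"):
            probs = predict_volume(m, v, axis, batch_size=4)
            assert probs.shape == v.shape
            assert (probs.data >= 0).all() and (probs.data <= 1).all()
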