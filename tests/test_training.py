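import numpy as np
import pytest

from pancseg.network import ModelConfig
from pancseg.synthetic import PhantomSpec, generate_dataset
from pancseg.training import (
    TrainConfig,
    build_slice_dataset,
    make_folds,
    train_stage,
)

TINY_MODEL = ModelConfig(
    in_size=(32, 32), n_blocks=2, base_channels=4, dense_layers=2, n3d_blocks=1
)


@pytest.fixture(scope="module")
def tiny_cases():
    return generate_dataset(4, PhantomSpec(shape=(32, 32, 24), seed=42))


class TestTrainConfig:
    def test_reference_defaults(self):
        cfg = TrainConfig()
        assert cfg.epochs == 30
        assert cfg.learning_rate == pytest.approx(1e-5)
        assert cfg.batch_size == 1
        assert cfg.val_fraction == pytest.approx(0.10)
        assert cfg.min_pancreas_pixels == 100
        assert cfg.folds == 4

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(val_fraction=0.0)
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)


class TestSliceDataset:
    def test_filter_and_scaling(self, tiny_cases):
        vols = [(c.image, c.mask) for c in tiny_cases]
        X, Y = build_slice_dataset(vols, "axial", (32, 32), min_pixels=20)
        assert X.shape[1:] == (3, 32, 32)
        assert Y.shape[1:] == (1, 32, 32)
        assert X.max() <= 1.0
        assert set(np.unique(Y)) <= {0.0, 1.0}

    def test_no_qualifying_slices(self, tiny_cases):
        vols = [(c.image, c.mask) for c in tiny_cases]
        with pytest.raises(ValueError, match="no qualifying"):
            build_slice_dataset(vols, "axial", (32, 32), min_pixels=10 ** 6)


class TestTrainStage:
    def test_learning_on_phantoms_and_determinism(self, tiny_cases):
        """Validation Dice loss drops over a short run, and an identical
        seed reproduces the loss history exactly."""
        vols = [(c.image, c.mask) for c in tiny_cases]
        cfg = TrainConfig(epochs=3, learning_rate=1e-3, seed=7, min_pancreas_pixels=20)
        model, hist = train_stage(vols, "axial", cfg, TINY_MODEL, stage="coarse")
        assert len(hist["train_loss"]) == 3
        assert np.isfinite(hist["train_loss"]).all()
        assert np.isfinite(hist["val_loss"]).all()
        assert hist["val_loss"][-1] < hist["val_loss"][0]

        _, hist2 = train_stage(vols, "axial", cfg, TINY_MODEL, stage="coarse")
        assert hist2["train_loss"] == hist["train_loss"]
        assert hist2["val_loss"] == hist["val_loss"]

    def test_validation_split_is_ten_percent(self):
        """100 training slices with val_fraction 0.10 yield exactly 10
        validation slices, disjoint from and complementary to training."""
        from pancseg.training import split_validation

        val, train = split_validation(100, 0.10, np.random.default_rng(0))
        assert len(val) == 10
        assert set(val).isdisjoint(train)
        assert sorted(np.concatenate([val, train])) == list(range(100))

    def test_case_level_validation_split(self, tiny_cases):
        """With val_split='case', validation slices come only from held-out
        cases and training still proceeds."""
        vols = [(c.image, c.mask) for c in tiny_cases]
        cfg = TrainConfig(epochs=1, learning_rate=1e-3, seed=0, val_split="case",
                          val_fraction=0.25, min_pancreas_pixels=10)
        model, hist = train_stage(vols, "axial", cfg, TINY_MODEL)
        assert len(hist["train_loss"]) == 1
        assert np.isfinite(hist["val_loss"][0])  # one case held out

    def test_too_few_volumes(self, tiny_cases):
        with pytest.raises(ValueError, match="at least 2"):
            train_stage([(tiny_cases[0].image, tiny_cases[0].mask)], "axial",
                        TrainConfig(), TINY_MODEL)


class TestCrossValidate:
    def test_each_case_tested_once_micro_scale(self, tiny_cases):
        """2-fold cross-validation of the full cascade at micro scale:
        every case is scored exactly once and fold assignment partitions
        the dataset."""
        from pancseg.training import cross_validate

        cfg = TrainConfig(
            epochs=1, learning_rate=1e-3, seed=0, folds=2, min_pancreas_pixels=10
        )
        out = cross_validate(tiny_cases, cfg, TINY_MODEL, margin=4)
        assert len(out["per_fold"]) == 2
        assert out["pooled"].n_cases == len(tiny_cases)
        assert sorted(out["case_scores"]) == sorted(c.case_id for c in tiny_cases)
        tested = sorted(i for fold in out["fold_assignment"] for i in fold)
        assert tested == list(range(len(tiny_cases)))
        assert 0.0 <= out["pooled"].mean <= 1.0


class TestMakeFolds:
    def test_partition_property(self):
        folds = make_folds(8, 4, seed=0)
        assert len(folds) == 4
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(8))
        assert all(len(f) == 2 for f in folds)

    def test_deterministic(self):
        a = make_folds(10, 3, seed=5)
        b = make_folds(10, 3, seed=5)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_balanced_sizes_82_cases(self):
        folds = make_folds(82, 4, seed=0)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 82

    def test_folds_exceed_cases(self):
        with pytest.raises(ValueError):
            make_folds(3, 4, seed=0)
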