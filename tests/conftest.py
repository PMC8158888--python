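import numpy as np
import pytest

from pancseg.volume_io import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    return Volume(data=rng.normal(size=(10, 12, 14)))


class OracleModel:
    """A 'model' that emits the ground-truth mask as probabilities.

    For cropped inputs it locates the crop offset inside the source image
    by matching voxel values, then returns the matching ground-truth crop.
    Used to test the cascade plumbing independently of any training.
    """

    def __init__(self, image: Volume, gt: Volume):
        self.image = image
        self.gt = gt

    def predict_volume(self, v: Volume, axis: str) -> Volume:
        if v.shape == self.gt.shape and np.array_equal(v.data, self.image.data):
            return Volume(data=self.gt.data.astype(np.float64))
        # locate the crop by matching its corner voxel, then verify
        corner = v.data[0, 0, 0]
        for off in np.argwhere(self.image.data == corner):
            sl = tuple(slice(o, o + s) for o, s in zip(off, v.shape))
            block = self.image.data[sl]
            if block.shape == v.shape and np.array_equal(block, v.data):
                return Volume(data=self.gt.data[sl].astype(np.float64))
        raise AssertionError("oracle could not locate the crop in the source image")


@pytest.fixture
def oracle_model_cls():
    return OracleModel
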