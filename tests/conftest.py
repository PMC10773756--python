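import numpy as np
import pytest

from driftstream import LabeledSeriesSet


@pytest.fixture
def toy_set() -> LabeledSeriesSet:
    """Four 3-point series, two classes."""
    return LabeledSeriesSet(
        values=np.array([[0.0, 1.0, 2.0], [1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [0.5, 1.5, 2.5]]),
        labels=np.array([0, 1, 1, 0]),
        class_names=("neg", "pos"),
        dataset_id="toy",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_random_set(rng, s=20, l=8, k=3) -> LabeledSeriesSet:
    return LabeledSeriesSet(
        values=rng.standard_normal((s, l)),
        labels=rng.integers(0, k, size=s),
        class_names=tuple(f"c{i}" for i in range(k)),
    )
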