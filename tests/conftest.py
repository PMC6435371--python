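import numpy as np
import pytest

from sanod import ComponentSet, Dataset, SpectralAxis, TimeAxis


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dataset(rng, n=None, t=None, with_sigma=True):
    """Small random dataset on an irregular-but-increasing spectral grid."""
    n = n or int(rng.integers(4, 40))
    t = t or int(rng.integers(1, 25))
    axis = SpectralAxis(np.cumsum(rng.uniform(0.01, 1.0, size=n)), "arbitrary", "q")
    times = TimeAxis(np.sort(rng.uniform(-1e-11, 1e-7, size=t)))
    signal = rng.normal(size=(n, t))
    sigma = rng.uniform(0.1, 2.0, size=(n, t)) if with_sigma else None
    return Dataset(axis, times, signal, sigma)


def random_components(rng, axis, k):
    return ComponentSet(
        axis=axis,
        matrix=rng.normal(size=(len(axis), k)),
        labels=tuple(f"c{i}" for i in range(k)),
        provenance=tuple("prior" for _ in range(k)),
    )


@pytest.fixture
def dataset_factory(rng):
    def make(**kwargs):
        return random_dataset(rng, **kwargs)

    return make
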