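import numpy as np
import pytest

from soilspec import SpectrumSet, NiTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_spectra(values, wl0: float = 400.0, ids=None) -> SpectrumSet:
    """SpectrumSet on a 1-nm grid starting at ``wl0`` from a 2-D array."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, b = values.shape
    if ids is None:
        ids = [f"S{i}" for i in range(n)]
    return SpectrumSet(ids, wl0 + np.arange(b, dtype=float), values)


@pytest.fixture
def small_set(rng) -> SpectrumSet:
    return make_spectra(rng.uniform(0.1, 0.9, size=(5, 20)))


@pytest.fixture
def small_ni(small_set) -> NiTable:
    rng = np.random.default_rng(99)
    return NiTable(small_set.sample_ids, rng.uniform(10, 70, size=small_set.n_samples))
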