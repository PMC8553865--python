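import datetime as dt

import numpy as np
import pytest

from cropcycles import AlgorithmConfig, EviSeries
from cropcycles.simulate import SyntheticParams, generate_pixel


@pytest.fixture
def config():
    return AlgorithmConfig()


@pytest.fixture
def clean_pixel():
    """Factory: a noise-free, cloud-free 3-year pixel of a given class."""

    def make(n_cycles, seed=0, **kwargs):
        params = SyntheticParams(
            n_cycles=n_cycles, noise_sd=0.0, cloud_prob=0.0, seed=seed, **kwargs
        )
        return generate_pixel(params, years=3)

    return make


@pytest.fixture
def noisy_pixel():
    """Factory: a pixel with the default noise and cloud conditions."""

    def make(n_cycles, seed=0, **kwargs):
        params = SyntheticParams(n_cycles=n_cycles, seed=seed, **kwargs)
        return generate_pixel(params, years=3)

    return make


def make_series(values, times=None, flags=None, interpolated=None, epoch=dt.date(2001, 1, 1)):
    values = np.asarray(values, dtype=float)
    n = len(values)
    if times is None:
        times = np.arange(n) * 16
    if flags is None:
        flags = np.zeros(n, dtype=int)
    if interpolated is None:
        interpolated = np.zeros(n, dtype=bool)
    return EviSeries(times=times, values=values, flags=flags, interpolated=interpolated, epoch=epoch)
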