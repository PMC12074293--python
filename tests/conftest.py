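import numpy as np
import pytest

from tremorkit import SimConfig, simulate_tremor
from tremorkit.signal_io import AccelSeries, UNIT_MS2


def make_tone_series(
    f0: float = 5.0,
    amplitude: float = 1.0,
    noise_sigma: float = 0.0,
    duration_s: float = 60.0,
    seed: int = 0,
    **kwargs,
) -> AccelSeries:
    cfg = SimConfig(
        tremor_frequency_hz=f0,
        tremor_amplitude=amplitude,
        noise_sigma=noise_sigma,
        duration_s=duration_s,
        seed=seed,
        **kwargs,
    )
    return simulate_tremor(cfg)


def series_from_arrays(x, y, z, fs=55.56, units=UNIT_MS2, **kwargs) -> AccelSeries:
    n = len(x)
    return AccelSeries(
        timestamps=np.arange(n) / fs,
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
        z=np.asarray(z, dtype=float),
        units=units,
        nominal_rate_hz=fs,
        **kwargs,
    )


@pytest.fixture
def tone_5hz() -> AccelSeries:
    return make_tone_series(5.0, 1.0, noise_sigma=0.05, seed=7)


@pytest.fixture
def quiet_tone_5hz() -> AccelSeries:
    return make_tone_series(5.0, 1.0, noise_sigma=0.0, seed=0)
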