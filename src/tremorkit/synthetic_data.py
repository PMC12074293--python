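"""Synthetic tri-axial accelerometer recordings with known ground truth.

Recordings are built as gravity offset + tremor tone (plus optional
harmonics) + low-frequency drift + voluntary-motion components + white
Gaussian sensor noise, each distributed across the axes by unit vectors.
Calibration fixtures emulate the six static orientations with configurable
per-axis bias and scale errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .signal_io import AccelSeries, DEFAULT_RATE_HZ, G_TO_MS2, UNIT_G, UNIT_MS2

__all__ = [
    "SimConfig",
    "CalibrationSimConfig",
    "NyquistError",
    "simulate_tremor",
    "simulate_six_positions",
    "scenario_preset",
    "ORIENTATION_LABELS",
]

ORIENTATION_LABELS = ("+x", "-x", "+y", "-y", "+z", "-z")

_UNIT_NORM_TOL = 1e-9


class NyquistError(ValueError):
    """A requested component frequency violates the sampling theorem."""


def _check_unit(vec: np.ndarray, name: str) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector")
    norm = float(np.linalg.norm(vec))
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"{name} must have unit norm (got |v| = {norm:.6g})")
    return vec


@dataclass
class SimConfig:
    """Parameterization of one synthetic tremor recording.

    All amplitudes are in m/s^2; the generated series is in m/s^2 with the
    static gravity offset included, mimicking a raw (unit-converted) log.
    """

    tremor_frequency_hz: float = 5.0
    tremor_amplitude: float = 1.0
    tremor_axis_weights: tuple[float, float, float] = (0.0, 0.0, 1.0)
    harmonics: Sequence[tuple[float, float]] = ()
    drift_amplitude: float = 0.0
    drift_frequency_hz: float = 0.2
    linear_trend: float = 0.0  # m/s^2 over the full duration, along the weights
    voluntary: Sequence[tuple[float, float]] = ()
    gravity_orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)
    noise_sigma: float = 0.0
    duration_s: float = 60.0
    sampling_rate_hz: float = DEFAULT_RATE_HZ
    timestamp_jitter_s: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        nyq = self.sampling_rate_hz / 2.0
        if self.tremor_amplitude > 0 and not self.tremor_frequency_hz < nyq:
            raise NyquistError(
                f"tremor frequency {self.tremor_frequency_hz} Hz is not below "
                f"the Nyquist frequency {nyq} Hz"
            )
        for mult, _amp in self.harmonics:
            f = mult * self.tremor_frequency_hz
            if not f < nyq:
                raise NyquistError(
                    f"harmonic at {f} Hz is not below the Nyquist frequency {nyq} Hz"
                )
        for f, _amp in self.voluntary:
            if not f < nyq:
                raise NyquistError(
                    f"voluntary component at {f} Hz is not below the Nyquist "
                    f"frequency {nyq} Hz"
                )
        if not (0 <= self.drift_frequency_hz < 1.0):
            raise ValueError("drift_frequency_hz must lie in [0, 1)")
        _check_unit(self.tremor_axis_weights, "tremor_axis_weights")
        _check_unit(self.gravity_orientation, "gravity_orientation")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        for name in ("tremor_amplitude", "drift_amplitude", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def simulate_tremor(config: SimConfig) -> AccelSeries:
    """Generate a recording per ``config``; identical config => identical bits.

    The tremor tone, its harmonics, drift and voluntary components all ride on
    ``tremor_axis_weights``; gravity rides on ``gravity_orientation``.
    Component phases are drawn from the seeded generator, so two recordings
    with different seeds differ in phase as well as noise.
    """
    config.validate()
    fs = config.sampling_rate_hz
    n = int(config.duration_s * fs)
    if n < 1:
        raise ValueError("duration too short for one sample at this rate")
    rng = np.random.default_rng(config.seed)

    t = np.arange(n) / fs
    if config.timestamp_jitter_s > 0:
        jitter = rng.uniform(-config.timestamp_jitter_s, config.timestamp_jitter_s, n)
        jitter[0] = 0.0
        t = np.sort(t + jitter)

    # phases drawn in a fixed order so the stream layout is reproducible
    tone_phase = rng.uniform(0, 2 * np.pi)
    harm_phases = rng.uniform(0, 2 * np.pi, len(config.harmonics))
    drift_phase = rng.uniform(0, 2 * np.pi)
    vol_phases = rng.uniform(0, 2 * np.pi, len(config.voluntary))

    scalar = config.tremor_amplitude * np.sin(
        2 * np.pi * config.tremor_frequency_hz * t + tone_phase
    )
    for (mult, rel), ph in zip(config.harmonics, harm_phases):
        scalar = scalar + (config.tremor_amplitude * rel) * np.sin(
            2 * np.pi * mult * config.tremor_frequency_hz * t + ph
        )
    if config.drift_amplitude > 0:
        scalar = scalar + config.drift_amplitude * np.sin(
            2 * np.pi * config.drift_frequency_hz * t + drift_phase
        )
    if config.linear_trend != 0.0:
        scalar = scalar + config.linear_trend * (t / t[-1] if n > 1 else t)
    for (f, amp), ph in zip(config.voluntary, vol_phases):
        scalar = scalar + amp * np.sin(2 * np.pi * f * t + ph)

    w = np.asarray(config.tremor_axis_weights, dtype=float)
    g = np.asarray(config.gravity_orientation, dtype=float)
    data = scalar[:, None] * w[None, :] + G_TO_MS2 * g[None, :]
    if config.noise_sigma > 0:
        data = data + rng.normal(0.0, config.noise_sigma, size=(n, 3))

    return AccelSeries(
        timestamps=t,
        x=data[:, 0],
        y=data[:, 1],
        z=data[:, 2],
        units=UNIT_MS2,
        nominal_rate_hz=fs,
        provenance=f"simulate_tremor(seed={config.seed})",
    )


@dataclass
class CalibrationSimConfig:
    """Parameterization of six-orientation static calibration fixtures."""

    true_bias: tuple[float, float, float] = (0.0, 0.0, 0.0)  # g
    true_scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sigma_g: float = 0.0
    duration_s: float = 30.0
    sampling_rate_hz: float = DEFAULT_RATE_HZ
    seed: int = 0

    def validate(self) -> None:
        scale = np.asarray(self.true_scale, dtype=float)
        if scale.shape != (3,) or np.any(scale <= 0):
            raise ValueError("true_scale components must be positive")
        if np.asarray(self.true_bias, dtype=float).shape != (3,):
            raise ValueError("true_bias must be a 3-vector")
        if self.noise_sigma_g < 0:
            raise ValueError("noise_sigma_g must be non-negative")
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("duration and rate must be positive")


def _orientation_vector(label: str) -> np.ndarray:
    sign = 1.0 if label[0] == "+" else -1.0
    axis = "xyz".index(label[1])
    v = np.zeros(3)
    v[axis] = sign
    return v


def simulate_six_positions(
    config: CalibrationSimConfig,
) -> dict[str, AccelSeries]:
    """Six static recordings, one per ±axis orientation, in g units.

    For orientation label ``k`` the noiseless reading is
    ``scale * gravity_k + bias`` where ``gravity_k`` is ±1 g on the aligned
    axis and zero elsewhere.
    """
    config.validate()
    fs = config.sampling_rate_hz
    n = int(config.duration_s * fs)
    bias = np.asarray(config.true_bias, dtype=float)
    scale = np.asarray(config.true_scale, dtype=float)
    rng = np.random.default_rng(config.seed)
    t = np.arange(n) / fs

    out: dict[str, AccelSeries] = {}
    for label in ORIENTATION_LABELS:
        truth = _orientation_vector(label)
        clean = scale * truth + bias
        data = np.tile(clean, (n, 1))
        if config.noise_sigma_g > 0:
            data = data + rng.normal(0.0, config.noise_sigma_g, size=(n, 3))
        out[label] = AccelSeries(
            timestamps=t.copy(),
            x=data[:, 0],
            y=data[:, 1],
            z=data[:, 2],
            units=UNIT_G,
            nominal_rate_hz=fs,
            provenance=f"simulate_six_positions(seed={config.seed}, orientation={label})",
        )
    return out


# ---------------------------------------------------------------------------
# clinical-scenario presets
# ---------------------------------------------------------------------------

#: Dominant-frequency regimes per test id: resting tests sit in the classic
#: 3-7 Hz band, unsupported-posture tests shift up to 5-9 Hz, and the active
#: tasks mix a 3-8 Hz tremor with sub-2 Hz voluntary motion.
_TEST_FREQ_RANGES = {
    1: (3.0, 7.0),
    2: (5.0, 9.0),
    3: (3.0, 7.0),
    4: (5.0, 9.0),
    5: (3.0, 8.0),
    6: (3.0, 8.0),
}
_ACTIVE_TESTS = (5, 6)
_CONTROL_FREQ_RANGE = (3.0, 6.0)

#: Tremor tone amplitudes (m/s^2).  The control value is an order-of-magnitude
#: choice for physiological tremor, not calibrated to any cohort.
_SEVERITY_AMPLITUDE = {"control": 0.2, "mild": 1.0, "strong": 2.5}

_SEVERITY_CODE = {"control": 0, "mild": 1, "strong": 2}


def scenario_preset(test_id: int, severity: str = "mild", seed: int = 0) -> SimConfig:
    """A :class:`SimConfig` emulating one clinical test at a given severity.

    Deterministic in ``(test_id, severity, seed)``.  Tests 5 and 6 always
    include at least one voluntary component below 2 Hz.
    """
    if test_id not in _TEST_FREQ_RANGES:
        raise ValueError(f"unknown test_id {test_id!r}; expected 1..6")
    if severity not in _SEVERITY_AMPLITUDE:
        raise ValueError(
            f"unknown severity {severity!r}; expected one of {sorted(_SEVERITY_AMPLITUDE)}"
        )
    rng = np.random.default_rng([seed, test_id, _SEVERITY_CODE[severity]])

    lo, hi = _CONTROL_FREQ_RANGE if severity == "control" else _TEST_FREQ_RANGES[test_id]
    f0 = float(rng.uniform(lo, hi))
    amplitude = _SEVERITY_AMPLITUDE[severity]

    voluntary: list[tuple[float, float]] = []
    if test_id in _ACTIVE_TESTS:
        # writing/waving: one or two slow, large components below 2 Hz
        n_vol = int(rng.integers(1, 3))
        for _ in range(n_vol):
            voluntary.append(
                (float(rng.uniform(0.5, 1.9)), float(rng.uniform(0.5, 1.5)) * max(amplitude, 0.5))
            )

    # random tremor direction, mildly tilted gravity
    w = rng.normal(size=3)
    w /= np.linalg.norm(w)
    g = np.array([0.0, 0.0, 1.0]) + 0.05 * rng.normal(size=3)
    g /= np.linalg.norm(g)

    return SimConfig(
        tremor_frequency_hz=f0,
        tremor_amplitude=amplitude,
        tremor_axis_weights=tuple(w),
        drift_amplitude=0.3 if test_id in _ACTIVE_TESTS else 0.1,
        drift_frequency_hz=float(rng.uniform(0.05, 0.5)),
        voluntary=tuple(voluntary),
        gravity_orientation=tuple(g),
        noise_sigma=0.05,
        duration_s=60.0,
        sampling_rate_hz=DEFAULT_RATE_HZ,
        seed=seed,
    )
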