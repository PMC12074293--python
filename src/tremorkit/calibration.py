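"""Six-position static calibration and dynamic single-tone validation.

The sensor model is ``measured = scale * true + bias`` per axis.  With the
aligned-axis time averages ``m+`` (axis up, +1 g) and ``m-`` (axis down,
-1 g) the two-point estimator is ``bias = (m+ + m-) / 2`` and
``scale = (m+ - m-) / 2`` — exact for noise-free fixtures.  Cross-axis
misalignment is not modelled; six positions cannot identify it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import preprocess as pp
from .preprocess import PreprocessConfig, run_preprocess
from .signal_io import AccelSeries, UNIT_G, UNIT_MS2, convert_units
from .spectral import SpectralConfig, dominant_frequency, compute_spectra, tone_amplitude
from .synthetic_data import ORIENTATION_LABELS

__all__ = [
    "CalibrationModel",
    "DeviationReport",
    "six_position_calibrate",
    "apply_calibration",
    "estimate_tone",
    "dynamic_validation",
]

_AXIS_OF = {"x": 0, "y": 1, "z": 2}


@dataclass
class CalibrationModel:
    """Per-axis bias (g) and gain, plus post-fit residuals per orientation."""

    bias: np.ndarray  # (3,), g
    scale: np.ndarray  # (3,), dimensionless
    residual_report: dict[str, float]  # orientation label -> | |aligned mean| - 1 | in g

    def __post_init__(self) -> None:
        self.bias = np.asarray(self.bias, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if self.bias.shape != (3,) or self.scale.shape != (3,):
            raise ValueError("bias and scale must be 3-vectors")
        if np.any(self.scale <= 0):
            raise ValueError("scale components must be positive")
        if set(self.residual_report) != set(ORIENTATION_LABELS):
            raise ValueError("residual_report must cover all six orientations")

    @property
    def max_residual_g(self) -> float:
        return max(self.residual_report.values())

    def to_dict(self) -> dict:
        return {
            "bias_g": self.bias.tolist(),
            "scale": self.scale.tolist(),
            "residual_report_g": dict(self.residual_report),
        }


def _aligned_mean(series: AccelSeries, label: str) -> float:
    axis = _AXIS_OF[label[1]]
    return float(series.as_matrix()[:, axis].mean())


def six_position_calibrate(series_by_label: dict[str, AccelSeries]) -> CalibrationModel:
    """Estimate per-axis bias and scale from six labelled static recordings.

    Whole-recording means are used per orientation.  Residuals are reported
    after applying the recovered model: for each orientation, the absolute
    deviation of the calibrated aligned-axis mean magnitude from 1 g.
    """
    labels = set(series_by_label)
    if labels != set(ORIENTATION_LABELS):
        missing = sorted(set(ORIENTATION_LABELS) - labels)
        extra = sorted(labels - set(ORIENTATION_LABELS))
        raise ValueError(
            f"need exactly the six orientations {ORIENTATION_LABELS}; "
            f"missing {missing}, unexpected {extra}"
        )
    for label, s in series_by_label.items():
        if len(s) == 0:
            raise ValueError(f"orientation {label}: empty series")
        if s.units != UNIT_G:
            raise ValueError(f"orientation {label}: series must be in g units, got {s.units}")

    bias = np.zeros(3)
    scale = np.ones(3)
    for axis_name, axis in _AXIS_OF.items():
        m_pos = _aligned_mean(series_by_label[f"+{axis_name}"], f"+{axis_name}")
        m_neg = _aligned_mean(series_by_label[f"-{axis_name}"], f"-{axis_name}")
        bias[axis] = (m_pos + m_neg) / 2.0
        scale[axis] = (m_pos - m_neg) / 2.0
    if np.any(scale <= 0):
        raise ValueError(f"estimated non-positive scale {scale}; orientation labels likely swapped")

    model = CalibrationModel(bias=bias, scale=scale, residual_report={l: 0.0 for l in ORIENTATION_LABELS})
    residuals = {}
    for label, s in series_by_label.items():
        cal = apply_calibration(s, model)
        residuals[label] = abs(abs(_aligned_mean(cal, label)) - 1.0)
    model.residual_report = residuals
    return model


def apply_calibration(series: AccelSeries, model: CalibrationModel) -> AccelSeries:
    """Invert the sensor model: ``a_cal = (a_raw - bias) / scale`` per axis."""
    if series.units != UNIT_G:
        raise ValueError(f"calibration applies to g-unit series, got {series.units}")
    if series.calibrated:
        raise ValueError("series is already calibrated; refusing to apply twice")
    return series.with_log(
        "apply_calibration",
        x=(series.x - model.bias[0]) / model.scale[0],
        y=(series.y - model.bias[1]) / model.scale[1],
        z=(series.z - model.bias[2]) / model.scale[2],
        calibrated=True,
    )


# ---------------------------------------------------------------------------
# dynamic validation
# ---------------------------------------------------------------------------


@dataclass
class DeviationReport:
    """Per-trial and aggregate deviation metrics for single-tone trials."""

    trials: pd.DataFrame
    mean_abs_frequency_error_hz: float
    mean_signed_frequency_pct_error: float
    mean_abs_amplitude_pct_error: float
    max_abs_frequency_pct_error: float
    max_abs_amplitude_pct_error: float

    def to_frame(self) -> pd.DataFrame:
        return self.trials.copy()


def estimate_tone(
    series: AccelSeries,
    pre_config: PreprocessConfig | None = None,
    spec_config: SpectralConfig | None = None,
) -> tuple[float, float]:
    """(frequency Hz, peak amplitude m/s²) of a single-tone recording.

    Frequency comes from the dominant-axis interpolated PSD peak after the
    standard preprocessing chain; amplitude is the band-limited RMS estimate
    around that frequency, computed on the *unfiltered* (detrended) signal so
    filter attenuation does not bias it.
    """
    spec_config = spec_config or SpectralConfig()
    processed = run_preprocess(series, pre_config)
    spectra = compute_spectra(processed)
    freqs, axis = dominant_frequency(
        spectra,
        analysis_band=spec_config.analysis_band,
        prominence_factor=spec_config.prominence_factor,
        detection_smooth_hz=spec_config.detection_smooth_hz,
    )
    if axis is None:
        raise ValueError("no tone detected above the prominence floor")
    f_est = freqs[axis]
    unfiltered = pp.normalize(pp.detrend(pp.fill_gaps(convert_units(series, UNIT_MS2))))
    amp = tone_amplitude(unfiltered, f_est)
    return f_est, amp


def dynamic_validation(
    trials: list[tuple[AccelSeries, float, float]],
    pre_config: PreprocessConfig | None = None,
    spec_config: SpectralConfig | None = None,
) -> DeviationReport:
    """Run the tone estimators over (series, true_f_hz, true_amp) trials.

    Percentage deviations are ``100 * (est - true) / true``; the aggregate
    rows carry the mean absolute frequency error in Hz and the mean signed
    percentage error, matching the device-validation reporting convention.
    """
    if not trials:
        raise ValueError("dynamic_validation needs at least one trial")
    rows = []
    for series, f_true, a_true in trials:
        f_est, a_est = estimate_tone(series, pre_config, spec_config)
        rows.append(
            {
                "true_frequency_hz": f_true,
                "estimated_frequency_hz": f_est,
                "frequency_deviation_pct": 100.0 * (f_est - f_true) / f_true,
                "true_amplitude": a_true,
                "estimated_amplitude": a_est,
                "amplitude_deviation_pct": 100.0 * (a_est - a_true) / a_true,
            }
        )
    df = pd.DataFrame(rows)
    return DeviationReport(
        trials=df,
        mean_abs_frequency_error_hz=float(
            (df.estimated_frequency_hz - df.true_frequency_hz).abs().mean()
        ),
        mean_signed_frequency_pct_error=float(df.frequency_deviation_pct.mean()),
        mean_abs_amplitude_pct_error=float(df.amplitude_deviation_pct.abs().mean()),
        max_abs_frequency_pct_error=float(df.frequency_deviation_pct.abs().max()),
        max_abs_amplitude_pct_error=float(df.amplitude_deviation_pct.abs().max()),
    )
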