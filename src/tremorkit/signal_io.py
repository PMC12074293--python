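"""Reading and writing data-logger CSV recordings and cohort tables.

The logger format is one data line per sample: a timestamp field (either
numeric seconds or an ISO-8601 wall-clock stamp) followed by the x, y and z
acceleration values, comma separated.  Extra trailing fields are ignored.
Lines whose value fields fail to parse are kept as *gaps* (masked samples)
rather than dropped, so downstream gap-filling can repair them and sample
counts stay auditable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "G_TO_MS2",
    "UNIT_G",
    "UNIT_MS2",
    "AccelSeries",
    "PatientMeta",
    "LoggerFormatError",
    "EmptyLogError",
    "NoDataError",
    "NonMonotonicTimestampsError",
    "read_logger_csv",
    "write_logger_csv",
    "convert_units",
    "load_cohort_tables",
    "parse_band",
    "format_band",
]

#: Conversion constant between gravity units and m/s^2.
G_TO_MS2 = 9.81

UNIT_G = "g"
UNIT_MS2 = "m_per_s2"
_VALID_UNITS = (UNIT_G, UNIT_MS2)

#: Decimal places written by :func:`write_logger_csv`.  Below sensor
#: resolution, so write/read round-trips are stable.
CSV_PRECISION = 6

DEFAULT_RATE_HZ = 55.56


class LoggerFormatError(ValueError):
    """Base class for logger-CSV parsing failures."""


class EmptyLogError(LoggerFormatError):
    """The file contains no lines at all."""


class NoDataError(LoggerFormatError):
    """The file contains lines but none could be parsed as samples."""


class NonMonotonicTimestampsError(LoggerFormatError):
    """Parsed timestamps are not strictly increasing."""


@dataclass
class AccelSeries:
    """A uniformly sampled tri-axial acceleration recording.

    Attributes
    ----------
    timestamps:
        Seconds since recording start, strictly increasing.
    x, y, z:
        Per-axis acceleration samples, in ``units``.
    units:
        Either ``"g"`` or ``"m_per_s2"``.
    nominal_rate_hz:
        The sampling rate the recording was made at.
    gap_mask:
        Boolean flag per sample; ``True`` marks samples that were missing or
        corrupted in the source and were (or still need to be) filled.
    provenance:
        Free text describing where the data came from (file path, sim seed).
    calibrated:
        Set once a calibration model has been applied; guards double
        application.
    processing_log:
        Ordered record of the transformations applied so far.
    """

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    units: str = UNIT_MS2
    nominal_rate_hz: float = DEFAULT_RATE_HZ
    gap_mask: np.ndarray | None = None
    provenance: str = ""
    calibrated: bool = False
    gaps_filled: bool = False
    processing_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.timestamps.shape, dtype=bool)
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        n = len(self.timestamps)
        for name in ("x", "y", "z", "gap_mask"):
            if len(getattr(self, name)) != n:
                raise ValueError(
                    f"length mismatch: {name} has {len(getattr(self, name))} "
                    f"samples, timestamps has {n}"
                )
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise NonMonotonicTimestampsError(
                "timestamps must be strictly increasing"
            )
        if self.units not in _VALID_UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {_VALID_UNITS}")
        if not self.nominal_rate_hz > 0:
            raise ValueError("nominal_rate_hz must be positive")

    # -- convenience -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration_s(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])

    def as_matrix(self) -> np.ndarray:
        """Samples as an (n, 3) array in axis order x, y, z."""
        return np.column_stack([self.x, self.y, self.z])

    def replace(self, **changes) -> "AccelSeries":
        """A copy of this series with the given fields replaced."""
        base = {
            "timestamps": self.timestamps.copy(),
            "x": self.x.copy(),
            "y": self.y.copy(),
            "z": self.z.copy(),
            "units": self.units,
            "nominal_rate_hz": self.nominal_rate_hz,
            "gap_mask": self.gap_mask.copy(),
            "provenance": self.provenance,
            "calibrated": self.calibrated,
            "gaps_filled": self.gaps_filled,
            "processing_log": list(self.processing_log),
        }
        base.update(changes)
        return AccelSeries(**base)

    def with_log(self, entry: str, **changes) -> "AccelSeries":
        out = self.replace(**changes)
        out.processing_log.append(entry)
        return out


@dataclass(frozen=True)
class PatientMeta:
    """One demographic row (patient or control)."""

    patient_id: int
    age: int
    gender: str
    years_diagnosed: float | None
    medication: str
    dominant_hand: str
    group: str = "PD"  # "PD" or "control"

    def __post_init__(self) -> None:
        if not 0 <= self.age <= 120:
            raise ValueError(f"implausible age {self.age}")
        if self.group == "PD":
            if self.years_diagnosed is None or self.years_diagnosed < 0:
                raise ValueError("PD rows need a non-negative years_diagnosed")
        elif self.group == "control":
            if self.years_diagnosed is not None:
                raise ValueError("control rows must not carry years_diagnosed")
        else:
            raise ValueError(f"unknown group {self.group!r}")


# ---------------------------------------------------------------------------
# logger CSV
# ---------------------------------------------------------------------------


def _parse_timestamp(tok: str) -> float | None:
    tok = tok.strip()
    if not tok:
        return None
    try:
        return float(tok)
    except ValueError:
        pass
    try:
        return datetime.fromisoformat(tok).timestamp()
    except ValueError:
        return None


def read_logger_csv(path: str | Path, units: str = UNIT_G) -> AccelSeries:
    """Parse a logger CSV file into an :class:`AccelSeries`.

    Parameters
    ----------
    path:
        File to read.  Lines starting with ``#`` are treated as comments; a
        single leading header line (non-parseable timestamp) is tolerated.
    units:
        Units the file's values are in (``"g"`` by default — the device logs
        raw sensor units).  A ``# units:`` comment in the file overrides this.

    Lines whose acceleration fields do not parse are retained as masked gap
    samples (values NaN) so that the output length equals the number of data
    lines.  Timestamps are normalized to start at zero.
    """
    path = Path(path)
    raw = path.read_text(encoding="utf-8").splitlines()
    if not raw:
        raise EmptyLogError(f"{path}: file is empty")

    file_units = None
    rate = DEFAULT_RATE_HZ
    times: list[float] = []
    vals: list[tuple[float, float, float]] = []
    mask: list[bool] = []
    first_data_line = True
    for line in raw:
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.lower().startswith("units:"):
                file_units = body.split(":", 1)[1].strip()
            elif body.lower().startswith("rate_hz:"):
                rate = float(body.split(":", 1)[1])
            continue
        fields = stripped.split(",")
        ts = _parse_timestamp(fields[0])
        if ts is None:
            if first_data_line:
                # header row such as "timestamp,x,y,z"
                first_data_line = False
                continue
            # mid-file corrupted timestamp: keep as gap, interpolate later
            times.append(np.nan)
            vals.append((np.nan, np.nan, np.nan))
            mask.append(True)
            continue
        first_data_line = False
        if len(fields) < 4:
            times.append(ts)
            vals.append((np.nan, np.nan, np.nan))
            mask.append(True)
            continue
        try:
            xyz = (float(fields[1]), float(fields[2]), float(fields[3]))
            bad = any(not np.isfinite(v) for v in xyz)
        except ValueError:
            xyz = (np.nan, np.nan, np.nan)
            bad = True
        times.append(ts)
        vals.append(xyz)
        mask.append(bad)

    if not times:
        raise NoDataError(f"{path}: no parseable data lines")

    t = np.asarray(times, dtype=float)
    if np.isnan(t).all():
        raise NoDataError(f"{path}: no line has a parseable timestamp")
    # repair missing timestamps by linear interpolation over line index
    if np.isnan(t).any():
        idx = np.arange(len(t))
        ok = ~np.isnan(t)
        t[~ok] = np.interp(idx[~ok], idx[ok], t[ok])
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise NonMonotonicTimestampsError(f"{path}: timestamps are not strictly increasing")
    t = t - t[0]

    arr = np.asarray(vals, dtype=float)
    use_units = file_units if file_units in _VALID_UNITS else units
    return AccelSeries(
        timestamps=t,
        x=arr[:, 0],
        y=arr[:, 1],
        z=arr[:, 2],
        units=use_units,
        nominal_rate_hz=rate,
        gap_mask=np.asarray(mask, dtype=bool),
        provenance=str(path),
    )


def write_logger_csv(series: AccelSeries, path: str | Path) -> Path:
    """Write a series in the logger CSV format.

    Masked (gap) samples are written with empty value fields so they round-trip
    back into gaps.  Output is deterministic for a given series.
    """
    path = Path(path)
    fmt = f"%.{CSV_PRECISION}f"
    lines = [
        f"# units: {series.units}",
        f"# rate_hz: {series.nominal_rate_hz:g}",
        "timestamp,x,y,z",
    ]
    for i in range(len(series)):
        ts = fmt % series.timestamps[i]
        if series.gap_mask[i]:
            lines.append(f"{ts},,,")
        else:
            lines.append(
                f"{ts},{fmt % series.x[i]},{fmt % series.y[i]},{fmt % series.z[i]}"
            )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def convert_units(series: AccelSeries, target_units: str) -> AccelSeries:
    """Convert between g and m/s^2 (1 g = 9.81 m/s^2). Idempotent."""
    if target_units not in _VALID_UNITS:
        raise ValueError(f"unknown units {target_units!r}; expected one of {_VALID_UNITS}")
    if series.units == target_units:
        return series.replace()
    factor = G_TO_MS2 if target_units == UNIT_MS2 else 1.0 / G_TO_MS2
    return series.with_log(
        f"convert_units:{series.units}->{target_units}",
        x=series.x * factor,
        y=series.y * factor,
        z=series.z * factor,
        units=target_units,
    )


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

_PATIENT_COLS = {"patient_id", "age", "gender", "years_diagnosed", "medication", "dominant_hand"}
_RESULT_COLS = {
    "patient_id",
    "test_id",
    "age",
    "years_diagnosed",
    "dominant_freq_x_hz",
    "dominant_freq_y_hz",
    "dominant_freq_z_hz",
    "energy_band_hz",
    "avg_amplitude_m_s2",
}


def _packaged(name: str):
    return resources.files("tremorkit.data").joinpath(name)


def parse_band(text: str) -> tuple[float, float] | None:
    """Parse an energy-band cell like ``"3.0-5.0"`` into ``(3.0, 5.0)``."""
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return None
    s = str(text).strip()
    if not s or s.lower() == "nan":
        return None
    parts = [p.strip() for p in s.replace("–", "-").split("-") if p.strip()]
    if len(parts) != 2:
        raise ValueError(f"cannot parse energy band {text!r}")
    return float(parts[0]), float(parts[1])


def format_band(band: tuple[float, float] | None) -> str:
    if band is None:
        return "NaN"
    return f"{band[0]:.1f}-{band[1]:.1f}"


def load_cohort_tables(
    patients_path: str | Path | None = None,
    results_path: str | Path | None = None,
) -> tuple[list[PatientMeta], pd.DataFrame]:
    """Load the demographics table and the per-test results table.

    With no arguments the packaged transcriptions of the study cohort are
    used.  Missing numeric cells become NaN (the "unable to perform" state);
    row counts are preserved.

    Returns the demographics as a list of :class:`PatientMeta` and the
    results as a DataFrame with one row per (patient, test), including parsed
    ``energy_band_lo_hz`` / ``energy_band_hi_hz`` columns.
    """
    psrc = patients_path if patients_path is not None else _packaged("patients.csv")
    rsrc = results_path if results_path is not None else _packaged("test_results.csv")

    pdf = pd.read_csv(psrc)
    missing = _PATIENT_COLS - set(pdf.columns)
    if missing:
        raise ValueError(f"demographics table missing columns: {sorted(missing)}")
    patients = [
        PatientMeta(
            patient_id=int(r.patient_id),
            age=int(r.age),
            gender=str(r.gender),
            years_diagnosed=float(r.years_diagnosed) if pd.notna(r.years_diagnosed) else None,
            medication=str(r.medication),
            dominant_hand=str(r.dominant_hand),
            group="PD" if pd.notna(r.years_diagnosed) else "control",
        )
        for r in pdf.itertuples()
    ]

    rdf = pd.read_csv(rsrc)
    if rdf.empty and not set(rdf.columns):
        # a completely empty results file yields an empty, well-formed table
        rdf = pd.DataFrame(columns=sorted(_RESULT_COLS))
    missing = _RESULT_COLS - set(rdf.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    dup = rdf.duplicated(subset=["patient_id", "test_id"])
    if dup.any():
        keys = rdf.loc[dup, ["patient_id", "test_id"]].values.tolist()
        raise ValueError(f"duplicate (patient_id, test_id) keys: {keys}")
    bands = [parse_band(v) for v in rdf["energy_band_hz"]]
    rdf = rdf.assign(
        energy_band_lo_hz=[b[0] if b else np.nan for b in bands],
        energy_band_hi_hz=[b[1] if b else np.nan for b in bands],
    )
    return patients, rdf


def load_control_table(path: str | Path | None = None) -> list[PatientMeta]:
    """Load the control-group demographics (packaged transcription by default)."""
    src = path if path is not None else _packaged("controls.csv")
    df = pd.read_csv(src)
    return [
        PatientMeta(
            patient_id=int(r.control_id),
            age=int(r.age),
            gender=str(r.gender),
            years_diagnosed=None,
            medication=str(r.medication),
            dominant_hand=str(r.dominant_hand),
            group="control",
        )
        for r in df.itertuples()
    ]
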