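"""Cohort assembly: per-test records, grouped aggregation, control comparison.

Aggregation pools individual non-missing band-average amplitudes across all
tests of all subjects in a group (not per-subject means) and reports the
pooled mean with the sample (n-1) standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .signal_io import format_band

__all__ = [
    "TestRecord",
    "GroupSummary",
    "AGE_BINS",
    "YEARS_DIAGNOSED_BINS",
    "records_from_table",
    "aggregate_by_age",
    "aggregate_by_years_diagnosed",
    "summaries_to_frame",
    "compare_to_control",
]

#: Age bins, closed on both ends, as used for the age-group summary table.
AGE_BINS: tuple[tuple[int, int], ...] = ((60, 64), (65, 69), (70, 74), (75, 79))

#: Years-since-diagnosis bins.
YEARS_DIAGNOSED_BINS: tuple[tuple[int, int], ...] = ((0, 4), (5, 8), (9, 12))


@dataclass
class TestRecord:
    """One (patient, clinical test) result row.

    Either every analysis field is present (``performed=True``) or every one
    is missing (``performed=False``) — partial rows are invalid.
    """

    __test__ = False  # keep pytest from collecting this as a test class

    patient_id: int
    test_id: int
    age: int | None = None
    years_diagnosed: float | None = None
    dominant_freq_x_hz: float = math.nan
    dominant_freq_y_hz: float = math.nan
    dominant_freq_z_hz: float = math.nan
    energy_band_hz: tuple[float, float] | None = None
    band_avg_amplitude: float = math.nan
    performed: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.test_id <= 6:
            raise ValueError(f"test_id must be 1..6, got {self.test_id}")
        if not self.performed:
            fields_missing = (
                math.isnan(self.dominant_freq_x_hz)
                and math.isnan(self.dominant_freq_y_hz)
                and math.isnan(self.dominant_freq_z_hz)
                and self.energy_band_hz is None
                and math.isnan(self.band_avg_amplitude)
            )
            if not fields_missing:
                raise ValueError("a not-performed record must have all analysis fields missing")

    @property
    def amplitude_or_nan(self) -> float:
        return self.band_avg_amplitude if self.performed else math.nan

    def to_row(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "test_id": self.test_id,
            "age": self.age,
            "years_diagnosed": self.years_diagnosed,
            "dominant_freq_x_hz": self.dominant_freq_x_hz,
            "dominant_freq_y_hz": self.dominant_freq_y_hz,
            "dominant_freq_z_hz": self.dominant_freq_z_hz,
            "energy_band_hz": format_band(self.energy_band_hz),
            "avg_amplitude_m_s2": self.band_avg_amplitude,
        }


@dataclass(frozen=True, eq=False)
class GroupSummary:
    """Pooled amplitude statistics for one group bin."""

    label: str
    n_values: int
    mean_amplitude: float  # NaN when n_values == 0
    sd_amplitude: float  # NaN when n_values < 2 (sample SD undefined)

    def __post_init__(self) -> None:
        if self.n_values < 0:
            raise ValueError("n_values must be non-negative")

    def __eq__(self, other) -> bool:
        # NaN-tolerant equality: an undefined SD equals an undefined SD
        if not isinstance(other, GroupSummary):
            return NotImplemented
        same = lambda a, b: (a == b) or (math.isnan(a) and math.isnan(b))
        return (
            self.label == other.label
            and self.n_values == other.n_values
            and same(self.mean_amplitude, other.mean_amplitude)
            and same(self.sd_amplitude, other.sd_amplitude)
        )


def records_from_table(results: pd.DataFrame) -> list[TestRecord]:
    """Convert a loaded results table into :class:`TestRecord` objects."""
    records = []
    for r in results.itertuples():
        amp = float(r.avg_amplitude_m_s2) if pd.notna(r.avg_amplitude_m_s2) else math.nan
        performed = not math.isnan(amp)
        band = None
        if pd.notna(getattr(r, "energy_band_lo_hz", np.nan)):
            band = (float(r.energy_band_lo_hz), float(r.energy_band_hi_hz))
        records.append(
            TestRecord(
                patient_id=int(r.patient_id),
                test_id=int(r.test_id),
                age=int(r.age) if pd.notna(r.age) else None,
                years_diagnosed=float(r.years_diagnosed) if pd.notna(r.years_diagnosed) else None,
                dominant_freq_x_hz=float(r.dominant_freq_x_hz) if pd.notna(r.dominant_freq_x_hz) else math.nan,
                dominant_freq_y_hz=float(r.dominant_freq_y_hz) if pd.notna(r.dominant_freq_y_hz) else math.nan,
                dominant_freq_z_hz=float(r.dominant_freq_z_hz) if pd.notna(r.dominant_freq_z_hz) else math.nan,
                energy_band_hz=band,
                band_avg_amplitude=amp,
                performed=performed,
            )
        )
    return records


def _summarize(label: str, values: Sequence[float]) -> GroupSummary:
    # sorted so the floating sum, hence the aggregate, is exactly
    # permutation invariant
    vals = np.sort(np.asarray(values, dtype=float))
    n = len(vals)
    mean = float(vals.mean()) if n else math.nan
    sd = float(vals.std(ddof=1)) if n >= 2 else math.nan
    return GroupSummary(label=label, n_values=n, mean_amplitude=mean, sd_amplitude=sd)


def _aggregate(
    records: Iterable[TestRecord],
    bins: Sequence[tuple[int, int]],
    key: str,
) -> list[GroupSummary]:
    pools: dict[str, list[float]] = {f"{lo}-{hi}": [] for lo, hi in bins}
    unbinned: list[float] = []
    for rec in records:
        if not rec.performed or math.isnan(rec.band_avg_amplitude):
            continue
        val = getattr(rec, key)
        if val is None:
            unbinned.append(rec.band_avg_amplitude)
            continue
        for lo, hi in bins:
            if lo <= val <= hi:
                pools[f"{lo}-{hi}"].append(rec.band_avg_amplitude)
                break
        else:
            unbinned.append(rec.band_avg_amplitude)
    out = [_summarize(label, vals) for label, vals in pools.items()]
    out.append(_summarize("unbinned", unbinned))
    return out


def aggregate_by_age(
    records: Iterable[TestRecord],
    bins: Sequence[tuple[int, int]] = AGE_BINS,
) -> list[GroupSummary]:
    """Pooled amplitude mean/SD per age bin (closed intervals).

    Records whose age falls outside every bin are collected under the final
    ``"unbinned"`` summary rather than dropped, so counts are conserved.
    """
    return _aggregate(records, bins, "age")


def aggregate_by_years_diagnosed(
    records: Iterable[TestRecord],
    bins: Sequence[tuple[int, int]] = YEARS_DIAGNOSED_BINS,
) -> list[GroupSummary]:
    """Pooled amplitude mean/SD per years-since-diagnosis bin."""
    return _aggregate(records, bins, "years_diagnosed")


def summaries_to_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [s.label for s in summaries],
            "n_values": [s.n_values for s in summaries],
            "mean_amplitude_m_s2": [s.mean_amplitude for s in summaries],
            "sd_amplitude_m_s2": [s.sd_amplitude for s in summaries],
        }
    )


@dataclass(frozen=True)
class ControlComparison:
    """Descriptive patient-vs-control comparison for one test."""

    test_id: int
    patient_band_hz: tuple[float, float] | None
    control_band_hz: tuple[float, float] | None
    patient_amplitude: float
    control_amplitude: float
    amplitude_ratio: float  # patient / control


def compare_to_control(patient: TestRecord, control: TestRecord) -> ControlComparison:
    """Compare a patient record with a control record from the same test."""
    if patient.test_id != control.test_id:
        raise ValueError(
            f"test_id mismatch: patient ran test {patient.test_id}, "
            f"control ran test {control.test_id}"
        )
    pa, ca = patient.amplitude_or_nan, control.amplitude_or_nan
    ratio = pa / ca if ca and not math.isnan(ca) and not math.isnan(pa) else math.nan
    return ControlComparison(
        test_id=patient.test_id,
        patient_band_hz=patient.energy_band_hz,
        control_band_hz=control.energy_band_hz,
        patient_amplitude=pa,
        control_amplitude=ca,
        amplitude_ratio=ratio,
    )
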