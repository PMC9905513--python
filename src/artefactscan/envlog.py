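"""Station-log summaries and volumetric aerial spore concentration.

Logs are CSV files with header ``timestamp,temperature_c,rh_pct,co2_ppm,light``
and ISO-8601 timestamps.  Diurnal extrema are read off the mean-by-clock-hour
profile (24 bins), matching how conservators quote "maximum around 3 p.m.".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InsufficientDataError

__all__ = [
    "STATION_COLUMNS",
    "SporeSample",
    "LogSummary",
    "read_station_log",
    "summarize_log",
    "spore_concentration",
]

STATION_COLUMNS = ["timestamp", "temperature_c", "rh_pct", "co2_ppm", "light"]
_VARIABLES = STATION_COLUMNS[1:]

#: Hourly profile range below which extrema are reported as flat/undefined.
_FLAT_TOL = 1e-9


@dataclass(frozen=True)
class SporeSample:
    """One volumetric spore-trap reading."""

    taxon: str
    count: int
    flow_lpm: float = 10.0
    duration_min: float = 15.0

    def concentration(self, correction: float = 1.0) -> float:
        return spore_concentration(self.count, self.flow_lpm, self.duration_min, correction)


@dataclass(frozen=True)
class LogSummary:
    """Per-variable means and clock hours of the diurnal extrema."""

    means: dict[str, float]
    peak_hour: dict[str, int | None]
    trough_hour: dict[str, int | None]
    flat: dict[str, bool]


def read_station_log(path: str | Path) -> pd.DataFrame:
    """Read and validate a station-log CSV."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = [c for c in STATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"station log missing columns: {missing}")
    if not df["timestamp"].is_monotonic_increasing or df["timestamp"].duplicated().any():
        raise ValueError("timestamps must be strictly increasing")
    if ((df["rh_pct"] < 0) | (df["rh_pct"] > 100)).any():
        raise ValueError("relative humidity outside [0, 100]")
    if (df["co2_ppm"] < 0).any():
        raise ValueError("negative CO2 concentration")
    return df


def summarize_log(records: pd.DataFrame) -> LogSummary:
    """Means plus diurnal extrema hours from the hourly-binned mean profile.

    Requires at least 24 hours of records.  Variables whose hourly profile is
    flat get ``None`` extrema and a flat flag.
    """
    df = records.sort_values("timestamp")
    span = df["timestamp"].iloc[-1] - df["timestamp"].iloc[0]
    if span < pd.Timedelta(hours=24):
        raise InsufficientDataError(
            f"log spans {span}; at least 24 h needed for a diurnal profile"
        )
    # bin by nearest clock hour so an extremum at h:00 sits in the middle of
    # bin h rather than on the boundary between bins h-1 and h
    frac = df["timestamp"].dt.hour + df["timestamp"].dt.minute / 60.0
    hours = np.floor(frac + 0.5).astype(int) % 24
    means: dict[str, float] = {}
    peak: dict[str, int | None] = {}
    trough: dict[str, int | None] = {}
    flat: dict[str, bool] = {}
    for var in _VARIABLES:
        means[var] = float(df[var].mean())
        profile = df.groupby(hours)[var].mean()
        if float(profile.max() - profile.min()) < _FLAT_TOL:
            peak[var] = trough[var] = None
            flat[var] = True
        else:
            peak[var] = int(profile.idxmax())
            trough[var] = int(profile.idxmin())
            flat[var] = False
    return LogSummary(means=means, peak_hour=peak, trough_hour=trough, flat=flat)


def spore_concentration(
    count: float,
    flow_lpm: float = 10.0,
    duration_min: float = 15.0,
    correction: float = 1.0,
) -> float:
    """Spores per cubic metre: ``count / (flow_lpm * duration_min / 1000)``.

    ``correction`` is a multiplicative trap-efficiency hook, default 1.0 (no
    correction applied).
    """
    if count < 0:
        raise ValueError("spore count cannot be negative")
    if flow_lpm <= 0 or duration_min <= 0:
        raise ValueError("flow rate and duration must be positive")
    volume_m3 = flow_lpm * duration_min / 1000.0
    return count / volume_m3 * correction
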