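"""Hourly air-quality table I/O, outlier screening, and polar feature building.

The universal input record is an *hourly table*: a :class:`pandas.DataFrame`
with a ``timestamp`` column (hourly, strictly increasing, no duplicates) and
the standard columns ``ws`` (wind speed, m/s), ``wd`` (wind direction,
degrees, direction the wind blows FROM), ``temp`` (deg C), ``rh`` (%), and
concentration columns ``pm25, pm10, nox, no2, co, so2`` (ug/m3 or as
delivered; units pass through unchanged). Missing values are allowed
everywhere except ``timestamp``.

Clustering operates on *polar features*: each retained hour is embedded as a
point ``(x, y, c)`` where ``x = r sin(theta)``, ``y = r cos(theta)``,
``theta`` is the wind direction and ``r`` is a radial variable -- wind speed
by default, or shifted temperature for sites where a ubiquitous cold-weather
source (residential wood burning) must be separated from traffic. ``c`` is
the pollutant concentration under analysis. The convention puts north at +y
and east at +x; the clustering itself is invariant to this fixed rotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MET_COLUMNS = ["ws", "wd", "temp", "rh"]
POLLUTANT_COLUMNS = ["pm25", "pm10", "nox", "no2", "co", "so2"]
STANDARD_COLUMNS = ["timestamp"] + MET_COLUMNS + POLLUTANT_COLUMNS

#: Physical caps used by :func:`screen_outliers`; values outside the
#: (lower, upper) interval are set missing. Concentrations share a zero floor.
DEFAULT_CAPS: dict[str, tuple[float, float]] = {
    "pm25": (0.0, 1000.0),
    "pm10": (0.0, 2000.0),
    "nox": (0.0, np.inf),
    "no2": (0.0, np.inf),
    "co": (0.0, np.inf),
    "so2": (0.0, np.inf),
    "ws": (0.0, 60.0),
    "wd": (0.0, 360.0),
    "rh": (0.0, 100.0),
    "temp": (-40.0, 55.0),
}


class HourlyTableError(ValueError):
    """Malformed hourly table (missing/duplicate timestamps, bad schema)."""


@dataclass
class QCReport:
    """Accounting of what outlier screening changed or flagged."""

    n_rows: int
    removed: dict[str, int] = field(default_factory=dict)
    flagged: dict[str, int] = field(default_factory=dict)
    missing_per_column: dict[str, int] = field(default_factory=dict)
    unparseable_cells: int = 0

    @property
    def total_removed(self) -> int:
        return int(sum(self.removed.values()))

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_rows": self.n_rows,
                "removed": self.removed,
                "flagged": self.flagged,
                "missing_per_column": self.missing_per_column,
                "unparseable_cells": self.unparseable_cells,
            },
            indent=2,
        )


@dataclass
class PolarFeatures:
    """Per-hour (x, y, c) embedding of an hourly table.

    ``data`` holds columns ``x, y, c`` indexed by the retained rows'
    timestamps; rows with any missing input (wd, radial variable, pollutant)
    are excluded and their count recorded. When ``standardized`` is True,
    each column has sample mean 0 and sample sd 1 and ``center``/``scale``
    hold the inverse-transform parameters.
    """

    data: pd.DataFrame
    pollutant: str
    radial_variable: str
    n_dropped: int
    standardized: bool = False
    center: pd.Series | None = None
    scale: pd.Series | None = None
    radial_shift: float = 0.0

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.data.index


def read_hourly_table(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read an hourly table CSV into a typed DataFrame.

    Parameters
    ----------
    path
        CSV file with a header row and ISO-8601 timestamps.
    column_map
        Optional mapping from file column names to the standard names
        (e.g. ``{"PM25": "pm25", "date": "timestamp"}``).

    Unparseable numeric cells become missing; their count is stored in
    ``df.attrs["unparseable_cells"]``. Duplicate timestamps are fatal.
    """
    # keep sentinel strings like "NA" visible so they can be counted as
    # unparseable rather than silently swallowed by the CSV reader
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    if column_map:
        df = df.rename(columns=column_map)
    if "timestamp" not in df.columns:
        raise HourlyTableError("hourly table has no 'timestamp' column")
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    dup = df["timestamp"][df["timestamp"].duplicated()]
    if len(dup):
        stamps = ", ".join(str(t) for t in dup.unique()[:10])
        raise HourlyTableError(f"duplicate timestamps: {stamps}")
    df = df.sort_values("timestamp").reset_index(drop=True)

    n_bad = 0
    for col in df.columns:
        if col == "timestamp":
            continue
        before = df[col].isna().sum()
        df[col] = pd.to_numeric(df[col], errors="coerce")
        n_bad += int(df[col].isna().sum() - before)
    df.attrs["unparseable_cells"] = n_bad
    return df


def write_hourly_table(df: pd.DataFrame, path) -> None:
    """Write an hourly table CSV (missing values as empty cells)."""
    out = df.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%d %H:%M")
    out.to_csv(path, index=False)


def screen_outliers(
    df: pd.DataFrame,
    caps: dict[str, tuple[float, float]] | None = None,
    spike_k: float = 10.0,
    spike_window: int = 24,
) -> tuple[pd.DataFrame, QCReport]:
    """Screen physically impossible values and flag spikes.

    Cap violations are set to missing cell-wise (the row survives, so met
    data outlive a bad pollutant cell). The spike rule -- value exceeding
    ``spike_k`` times the centered rolling median over ``spike_window``
    hours -- only flags, never modifies.
    """
    caps = DEFAULT_CAPS if caps is None else caps
    out = df.copy()
    report = QCReport(n_rows=len(df))

    for col, (lo, hi) in caps.items():
        if col not in out.columns:
            continue
        vals = out[col]
        neg = vals < lo
        high = vals > hi
        if col in POLLUTANT_COLUMNS and lo == 0.0:
            if neg.any():
                report.removed[f"negative concentration: {col}"] = int(neg.sum())
        elif neg.any():
            report.removed[f"below physical floor: {col}"] = int(neg.sum())
        if high.any():
            report.removed[f"above physical cap: {col}"] = int(high.sum())
        out.loc[neg | high, col] = np.nan

    for col in POLLUTANT_COLUMNS:
        if col not in out.columns:
            continue
        med = out[col].rolling(spike_window, center=True, min_periods=6).median()
        spikes = (out[col] > spike_k * med) & (med > 0)
        if spikes.any():
            report.flagged[f"spike: {col}"] = int(spikes.sum())

    report.missing_per_column = {
        c: int(out[c].isna().sum()) for c in out.columns if c != "timestamp"
    }
    report.unparseable_cells = int(df.attrs.get("unparseable_cells", 0))
    return out, report


def to_polar_features(
    df: pd.DataFrame,
    pollutant: str,
    radial_variable: str = "wind_speed",
) -> PolarFeatures:
    """Embed retained hours as (x, y, c) points for clustering.

    With ``radial_variable="wind_speed"`` the radius is ws; with
    ``"temperature"`` it is ``temp - min(temp)`` (shifted so r >= 0 while
    the angle stays the reported wind direction). Hours missing any of
    wd, the radial variable, or the pollutant are dropped.
    """
    if pollutant not in df.columns:
        raise KeyError(f"pollutant column not in table: {pollutant}")
    if radial_variable not in ("wind_speed", "temperature"):
        raise ValueError(f"unknown radial variable: {radial_variable}")

    rcol = "ws" if radial_variable == "wind_speed" else "temp"
    if rcol not in df.columns:
        raise KeyError(f"radial column not in table: {rcol}")

    sub = df[["timestamp", "wd", rcol, pollutant]].dropna()
    if sub.empty:
        raise HourlyTableError("no retained rows after dropping missing values")
    n_dropped = len(df) - len(sub)

    shift = 0.0
    r = sub[rcol].to_numpy(float)
    if radial_variable == "temperature":
        shift = float(r.min())
        r = r - shift
    theta = np.deg2rad(sub["wd"].to_numpy(float))
    data = pd.DataFrame(
        {"x": r * np.sin(theta), "y": r * np.cos(theta), "c": sub[pollutant].to_numpy(float)},
        index=pd.DatetimeIndex(sub["timestamp"], name="timestamp"),
    )
    return PolarFeatures(
        data=data,
        pollutant=pollutant,
        radial_variable=radial_variable,
        n_dropped=n_dropped,
        radial_shift=shift,
    )


def standardize(features: PolarFeatures) -> PolarFeatures:
    """Scale each of x, y, c to sample mean 0 and sample sd 1.

    Wind components and concentration live on different scales, so all
    three coordinates are standardized before k-means. Sample sd (ddof=1)
    is used. Idempotent up to floating point. A zero-variance coordinate is
    an error naming the coordinate.
    """
    if len(features.data) < 2:
        raise ValueError("standardize needs at least 2 rows")
    center = features.data.mean()
    scale = features.data.std(ddof=1)
    dead = scale[scale == 0].index.tolist()
    if dead:
        raise ValueError(f"zero variance: {', '.join(dead)}")
    data = (features.data - center) / scale
    if features.standardized:
        # composing the transforms keeps the inverse mapping exact
        center = features.center + center * features.scale
        scale = features.scale * scale
    return PolarFeatures(
        data=data,
        pollutant=features.pollutant,
        radial_variable=features.radial_variable,
        n_dropped=features.n_dropped,
        standardized=True,
        center=center,
        scale=scale,
        radial_shift=features.radial_shift,
    )
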