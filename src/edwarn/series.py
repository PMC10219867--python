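"""Hourly time-series containers and I/O.

An hourly series is a :class:`pandas.Series` of non-negative values indexed
by a timezone-naive :class:`pandas.DatetimeIndex` on exact hour marks.
Gaps (missing hours) are represented by absent index entries, never by NaN
rows; the helpers here validate that contract, read/write the on-disk CSV
format (``timestamp,value`` with ``#`` comment lines), and apply the
training-window gap policy used before model fitting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

HOUR = pd.Timedelta(hours=1)


class SeriesFormatError(ValueError):
    """Raised when a series violates the hourly-series contract."""


def validate_hourly(series: pd.Series) -> pd.Series:
    """Validate the hourly-series contract and return the series unchanged.

    Checks: datetime index, strictly increasing, aligned on hour marks,
    all values finite and >= 0.
    """
    if not isinstance(series.index, pd.DatetimeIndex):
        raise SeriesFormatError("hourly series requires a DatetimeIndex")
    if len(series) == 0:
        return series
    idx = series.index
    if not idx.is_monotonic_increasing or idx.has_duplicates:
        raise SeriesFormatError("timestamps must be strictly increasing")
    if ((idx.minute != 0) | (idx.second != 0) | (idx.microsecond != 0)).any():
        raise SeriesFormatError("timestamps must fall on exact hour marks")
    vals = np.asarray(series, dtype=float)
    if not np.isfinite(vals).all():
        raise SeriesFormatError("values must be finite (drop missing hours instead)")
    if (vals < 0).any():
        raise SeriesFormatError("values must be non-negative")
    return series


def read_series_csv(path) -> pd.Series:
    """Read a ``timestamp,value`` CSV (``#`` lines are comments)."""
    df = pd.read_csv(path, comment="#", parse_dates=["timestamp"])
    if not {"timestamp", "value"} <= set(df.columns):
        raise SeriesFormatError(f"{path}: expected columns 'timestamp' and 'value'")
    s = pd.Series(df["value"].to_numpy(dtype=float), index=pd.DatetimeIndex(df["timestamp"]))
    s.index.name = "timestamp"
    s.name = "value"
    return validate_hourly(s)


def write_series_csv(series: pd.Series, path, header_comments: list[str] | None = None) -> None:
    """Write a series as ``timestamp,value`` CSV with optional ``#`` header lines."""
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        fh.write("timestamp,value\n")
        for ts, v in series.items():
            fh.write(f"{ts.isoformat()},{v:g}\n")


def contiguous_runs(series: pd.Series) -> list[pd.Series]:
    """Split a validated hourly series into maximal contiguous hourly runs."""
    if len(series) == 0:
        return []
    breaks = np.flatnonzero(np.diff(series.index.asi8) != HOUR.value)
    pieces = np.split(np.arange(len(series)), breaks + 1)
    return [series.iloc[p] for p in pieces]


def prepare_training(series: pd.Series, max_gap_hours: int = 6) -> pd.Series:
    """Produce a contiguous training series under the gap policy.

    Gaps of at most ``max_gap_hours`` missing hours are filled by linear
    interpolation (keeping the seasonal index alignment intact); a longer
    gap truncates history, keeping only data after the end of the last long
    gap.  Returns a strictly hourly, gap-free series.
    """
    if len(series) == 0:
        return series
    full = series.reindex(pd.date_range(series.index[0], series.index[-1], freq="h"))
    isna = full.isna().to_numpy()
    if isna.any():
        # find runs of missing hours; a run longer than max_gap truncates
        edges = np.flatnonzero(np.diff(np.concatenate(([0], isna.view(np.int8), [0]))))
        starts, ends = edges[::2], edges[1::2]
        long_runs = (ends - starts) > max_gap_hours
        if long_runs.any():
            cut = ends[long_runs][-1]  # first index after last long gap
            full = full.iloc[cut:]
        full = full.interpolate(method="linear", limit_direction="both")
    full.name = series.name
    return full
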