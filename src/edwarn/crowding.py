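"""Quartile-based crowding definition on hourly ED occupancy.

A day is *crowded* when its daily peak occupancy (DPO, the highest
occupancy recorded that calendar day) falls in the most crowded quartile
of days; the operative occupancy threshold is the nearest-rank 75th
percentile of complete-day peaks.  An hour is crowded when occupancy
reaches (>=) the threshold; a 24-hour forecast window is crowded when any
of its hours is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class InsufficientDataError(ValueError):
    """Too few complete days to estimate the crowding threshold."""


@dataclass(frozen=True)
class CrowdingScheme:
    """Crowding quantile, derived occupancy threshold, and window length."""

    quantile: float = 0.75
    threshold: float = float("nan")
    window: int = 24

    def __post_init__(self):
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must be in (0, 1)")
        if self.window < 1:
            raise ValueError("window must be >= 1")


def daily_peak_occupancy(occupancy: pd.Series) -> pd.DataFrame:
    """Per-calendar-day peak occupancy table.

    Returns one row per observed day with columns ``peak`` (daily maximum),
    ``peak_hour`` (hour-of-day of the maximum, first on ties) and
    ``complete`` (True when all 24 hours of the day were observed).
    Incomplete days stay in the table but are excluded from threshold
    estimation.
    """
    if len(occupancy) == 0:
        return pd.DataFrame(columns=["peak", "peak_hour", "complete"],
                            index=pd.Index([], name="day"))
    days = occupancy.index.normalize()
    grouped = occupancy.groupby(days)
    peak = grouped.max()
    # idxmax returns the first timestamp attaining the max (tie rule: earliest)
    peak_hour = pd.Series(pd.DatetimeIndex(grouped.idxmax()).hour, index=peak.index)
    complete = grouped.count() == 24
    out = pd.DataFrame({"peak": peak, "peak_hour": peak_hour, "complete": complete})
    out.index.name = "day"
    return out


def crowding_threshold(dpo: pd.DataFrame, quantile: float = 0.75,
                       min_days: int = 8) -> float:
    """Nearest-rank quantile of complete-day peaks.

    The nearest-rank definition (the ``ceil(q*n)``-th order statistic)
    returns an observed occupancy level, so labeling a day crowded when its
    peak >= threshold marks at most a ``1-q`` fraction of days (ties can
    push it below exactly 25%).
    """
    peaks = np.sort(dpo.loc[dpo["complete"], "peak"].to_numpy(dtype=float))
    if len(peaks) < min_days:
        raise InsufficientDataError(
            f"need >= {min_days} complete days for the threshold, got {len(peaks)}")
    rank = int(np.ceil(quantile * len(peaks)))
    return float(peaks[rank - 1])


def fit_scheme(occupancy: pd.Series, quantile: float = 0.75,
               window: int = 24) -> CrowdingScheme:
    """Derive a :class:`CrowdingScheme` (threshold included) from actuals."""
    theta = crowding_threshold(daily_peak_occupancy(occupancy), quantile)
    return CrowdingScheme(quantile=quantile, threshold=theta, window=window)


def label_hours(occupancy: pd.Series, scheme: CrowdingScheme) -> pd.Series:
    """Binary per-hour crowding labels: 1 iff occupancy >= threshold.

    The returned series covers the full hourly range of the input; hours
    missing from the input get a missing (NaN) label.
    """
    if np.isnan(scheme.threshold):
        raise ValueError("scheme has no threshold; use fit_scheme first")
    if len(occupancy) == 0:
        return pd.Series(dtype=float)
    full = occupancy.reindex(
        pd.date_range(occupancy.index[0], occupancy.index[-1], freq="h"))
    labels = (full >= scheme.threshold).astype(float)
    labels[full.isna()] = np.nan
    return labels


def label_window(hour_labels: pd.Series, origin: pd.Timestamp,
                 window: int = 24) -> float:
    """Window label at a forecast origin: crowded iff any of the next
    ``window`` hours is crowded.

    Returns 1.0, 0.0, or NaN.  A window with missing hourly labels and no
    observed crowding is missing (not 0): downtime must not create false
    negatives.  An observed crowded hour labels the window 1 regardless of
    other missing hours.
    """
    idx = pd.date_range(origin + pd.Timedelta(hours=1), periods=window, freq="h")
    vals = hour_labels.reindex(idx)
    if (vals == 1.0).any():
        return 1.0
    if vals.isna().any():
        return float("nan")
    return 0.0
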