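"""Prospective forecasting harness.

At every forecast origin the harness (re)trains each model on all history
available *at* that origin — never on anything later — and writes 24 hourly
point forecasts per target into an append-only prediction store.  Origins a
model cannot serve (insufficient history, fitting failure) are skipped and
logged, mirroring how a deployed system keeps running through downtime.
Predictions are later aligned with realized actuals into evaluation rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crowding import CrowdingScheme, label_hours
from .ets import EtsSpec, HoltWinters, InsufficientHistoryError, FittingError
from .series import HOUR, prepare_training

logger = logging.getLogger(__name__)

STORE_COLUMNS = ["origin", "model_id", "target", "horizon", "yhat", "created_at"]
HORIZON = 24


@dataclass(frozen=True)
class SkipRecord:
    """One logged skipped origin with its reason code."""

    origin: pd.Timestamp
    model_id: str
    target: str
    reason: str  # "insufficient_history" | "fitting_failure"


class PredictionStore:
    """Append-only forecast store backed by a flat CSV table.

    Uniqueness key is (origin, model_id, target, horizon); appends of
    already-present keys are ignored, which makes re-running a completed
    schedule a no-op.
    """

    def __init__(self, df: pd.DataFrame | None = None):
        self._blocks: list[pd.DataFrame] = [] if df is None else [df.reset_index(drop=True)]
        self._df: pd.DataFrame | None = None

    @property
    def df(self) -> pd.DataFrame:
        if self._df is None:
            if self._blocks:
                self._df = pd.concat(self._blocks, ignore_index=True)
                self._blocks = [self._df]
            else:
                self._df = pd.DataFrame(columns=STORE_COLUMNS)
        return self._df

    @classmethod
    def load(cls, path) -> "PredictionStore":
        df = pd.read_csv(path, comment="#", parse_dates=["origin", "created_at"])
        missing = set(STORE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: prediction store missing columns {sorted(missing)}")
        yhat = pd.to_numeric(df["yhat"], errors="coerce")
        bad = df.index[~np.isfinite(yhat)]
        if len(bad):
            raise ValueError(f"{path}: non-numeric yhat at data row {bad[0] + 1}")
        df = df.assign(yhat=yhat)
        return cls(df[STORE_COLUMNS])

    def save(self, path) -> None:
        self.df.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.df)

    def complete_origins(self, model_id: str, target: str) -> set:
        """Origins already holding all 24 horizons for (model, target)."""
        sub = self.df[(self.df["model_id"] == model_id) & (self.df["target"] == target)]
        counts = sub.groupby("origin")["horizon"].nunique()
        return set(counts.index[counts >= HORIZON])

    def append_forecasts(self, origin: pd.Timestamp, model_id: str, target: str,
                         yhat: np.ndarray) -> int:
        """Append one origin's 24 forecasts; returns the number added."""
        block = pd.DataFrame({
            "origin": origin,
            "model_id": model_id,
            "target": target,
            "horizon": np.arange(1, HORIZON + 1),
            "yhat": np.asarray(yhat, dtype=float),
            "created_at": origin,
        })
        self._blocks.append(block)
        self._df = None
        return len(block)


def run_prospective(series_by_target: dict[str, pd.Series],
                    specs: dict[str, EtsSpec],
                    origins,
                    refit_stride: int = 1,
                    store: PredictionStore | None = None,
                    fit_seed: int = 0,
                    fit_starts: int = 5,
                    max_gap_hours: int = 6) -> tuple[PredictionStore, list[SkipRecord]]:
    """Run the hourly prospective schedule.

    Parameters
    ----------
    series_by_target : dict
        Target name -> full hourly actuals (e.g. ``{"arrivals": ..., "occupancy": ...}``).
        At each origin only values at or before the origin are visible.
    specs : dict
        Model id -> :class:`EtsSpec`.
    origins : iterable of timestamps
        Forecast origins (hour marks), typically every hour after a warm-up.
    refit_stride : int
        Hours between full parameter re-estimations.  Between refits the
        smoothing states are advanced through the new observations with the
        last fitted parameters, so forecasts always start from the most
        recent state.

    Returns the (possibly pre-loaded) store plus the skip log.
    """
    if store is None:
        store = PredictionStore()
    origins = sorted(pd.Timestamp(o) for o in origins)
    skips: list[SkipRecord] = []
    for model_id, spec in specs.items():
        for target, series in series_by_target.items():
            done = store.complete_origins(model_id, target)
            params = None
            last_fit = None
            for origin in origins:
                if origin in done:
                    continue
                history = prepare_training(series.loc[:origin], max_gap_hours)
                try:
                    model = HoltWinters.from_series(history, spec)
                except InsufficientHistoryError:
                    skips.append(SkipRecord(origin, model_id, target, "insufficient_history"))
                    continue
                try:
                    if params is None or (origin - last_fit) >= refit_stride * HOUR:
                        res = model.fit(n_starts=fit_starts, seed=fit_seed)
                        params = res.params
                        last_fit = origin
                    else:
                        res = model.filter(params)
                except (FittingError, FloatingPointError) as exc:
                    logger.warning("origin %s %s/%s: %s", origin, model_id, target, exc)
                    skips.append(SkipRecord(origin, model_id, target, "fitting_failure"))
                    continue
                yhat = np.asarray(res.forecast(HORIZON))
                store.append_forecasts(origin, model_id, target, yhat)
            logger.info("%s/%s: %d records, %d skips", model_id, target,
                        len(store), len(skips))
    return store, skips


def write_skip_log(skips: list[SkipRecord], path) -> None:
    pd.DataFrame([s.__dict__ for s in skips],
                 columns=["origin", "model_id", "target", "reason"]).to_csv(path, index=False)


def align(store: PredictionStore,
          actuals_by_target: dict[str, pd.Series],
          scheme: CrowdingScheme | None = None,
          occupancy_target: str = "occupancy") -> tuple[pd.DataFrame, int]:
    """Join predictions with realized actuals into evaluation rows.

    Each stored forecast is matched with the actual value at
    ``origin + horizon`` hours; rows whose actual was never observed are
    dropped (downtime semantics) and counted.  When a crowding ``scheme``
    is given, the occupancy crowding label at the target hour and the
    origin hour-of-day are attached.

    Returns ``(rows, n_dropped)``.
    """
    df = store.df.copy()
    if len(df) == 0:
        cols = ["origin", "model_id", "target", "horizon", "yhat",
                "y_actual", "hour_label", "origin_hour"]
        return pd.DataFrame(columns=cols), 0
    df["target_time"] = df["origin"] + pd.to_timedelta(df["horizon"], unit="h")
    pieces = []
    for target, actual in actuals_by_target.items():
        sub = df[df["target"] == target].copy()
        sub["y_actual"] = actual.reindex(sub["target_time"]).to_numpy()
        pieces.append(sub)
    out = pd.concat(pieces, ignore_index=True) if pieces else df.iloc[:0].copy()
    n_before = len(out)
    out = out[out["y_actual"].notna()].copy()
    n_dropped = n_before - len(out)
    if scheme is not None and occupancy_target in actuals_by_target:
        labels = label_hours(actuals_by_target[occupancy_target], scheme)
        out["hour_label"] = labels.reindex(out["target_time"]).to_numpy()
    else:
        out["hour_label"] = np.nan
    out["origin_hour"] = pd.DatetimeIndex(out["origin"]).hour
    out = out.drop(columns=["target_time", "created_at"]).reset_index(drop=True)
    return out, n_dropped
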