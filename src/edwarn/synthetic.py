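"""Synthetic emergency-department arrivals and occupancy.

The generator reproduces the statistical structure of hourly ED data from
a large combined ED so the whole forecasting and evaluation pipeline can
be exercised without hospital data:

* a diurnal arrival profile (nonhomogeneous Poisson, trough of ~2
  patients/h in the early morning, peak of ~13/h at 4 p.m.),
* i.i.d. log-normal day-to-day surge multipliers on afternoon/evening
  intensities (making daily peak occupancy variable enough for a
  top-quartile crowding definition, while keeping pre-midnight history
  uninformative about the coming day's surge),
* occupancy generated mechanistically as an infinite-server queue:
  each arrival draws a log-normal length of stay (truncated at 12 h so
  that no pre-midnight patient can still be present during the next
  afternoon's crowding hours -- the midnight no-skill property is then
  exact by construction) and occupancy at an hour is the number of
  patients present, lagging the arrival cycle naturally (occupancy trough
  ~22 patients in the early morning, peak ~74 in the late afternoon,
  ~4% of hours crowded under the quartile rule), and
* downtime injection (block outages plus sporadic missing hours).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


DEFAULT_START = "2022-01-01"


@dataclass(frozen=True)
class DiurnalProfile:
    """Arrival intensities (patients/hour) by hour of day."""

    lambda_by_hour: np.ndarray

    def __post_init__(self):
        lam = np.asarray(self.lambda_by_hour, dtype=float)
        if lam.shape != (24,):
            raise ValueError("lambda_by_hour must have length 24")
        if (lam < 0).any():
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "lambda_by_hour", lam)


@dataclass(frozen=True)
class SurgeModel:
    """I.i.d. multiplicative day effects on afternoon/evening intensities.

    ``effect_day ~ LogNormal(-sigma_day^2/2, sigma_day)`` (mean ~1), capped
    at ``max_effect`` (demand on an ED is bounded by its catchment and
    physical capacity), applied to arrival intensities within
    ``surge_hours``.  Independence across days is what makes crowding in
    the coming day unpredictable from pre-midnight history.
    """

    sigma_day: float = 0.22
    surge_hours: tuple[int, int] = (12, 23)  # inclusive hour-of-day range
    max_effect: float = 1.4

    def sample_effects(self, n_days: int, rng: np.random.Generator) -> np.ndarray:
        eff = rng.lognormal(mean=-self.sigma_day ** 2 / 2.0,
                            sigma=self.sigma_day, size=n_days)
        return np.minimum(eff, self.max_effect)

    def applies(self, hours: np.ndarray) -> np.ndarray:
        lo, hi = self.surge_hours
        return (hours >= lo) & (hours <= hi)


@dataclass(frozen=True)
class LosModel:
    """Log-normal length-of-stay distribution, truncated at ``max_hours``."""

    median_hours: float = 6.0
    sigma: float = 0.65
    max_hours: float = 12.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        los = rng.lognormal(mean=np.log(self.median_hours), sigma=self.sigma, size=n)
        return np.minimum(los, self.max_hours)


#: Default diurnal intensities, calibrated against the design anchors:
#: trough ~2/h at 05-06, peak 13/h at 16:00, occupancy median ~23 at the
#: 06-08 trough and ~74 at the 17-18 peak (see scripts/calibrate.py).
DEFAULT_LAMBDA = np.array([
    5.5, 4.8, 4.3, 3.8, 3.3, 2.0, 2.0, 3.0,        # 00-07
    5.5, 8.5, 10.8, 12.2, 12.6, 12.7, 12.8, 12.9,  # 08-15
    13.0, 11.5, 9.5, 6.5, 4.8, 3.8, 3.4, 3.2,      # 16-23
])


def default_profile() -> tuple[DiurnalProfile, SurgeModel, LosModel]:
    """Calibrated defaults reproducing the design seasonality anchors."""
    return DiurnalProfile(DEFAULT_LAMBDA.copy()), SurgeModel(), LosModel()


def _hourly_index(n_days: int, start: str) -> pd.DatetimeIndex:
    return pd.date_range(start, periods=n_days * 24, freq="h")


def simulate_arrivals(profile: DiurnalProfile, surge: SurgeModel, n_days: int,
                      seed: int, start: str = DEFAULT_START) -> pd.Series:
    """Nonhomogeneous Poisson hourly arrival counts.

    ``arrivals_t ~ Poisson(lambda[hour(t)] * day_effect[day(t)])`` with the
    day effect applied only within the surge hours.
    """
    if n_days < 0:
        raise ValueError("n_days must be >= 0")
    idx = _hourly_index(n_days, start)
    rng = np.random.default_rng(seed)
    effects = surge.sample_effects(n_days, rng)
    hours = np.asarray(idx.hour)
    lam = profile.lambda_by_hour[hours]
    day_of = np.arange(len(idx)) // 24
    mult = np.where(surge.applies(hours), effects[day_of] if n_days else 1.0, 1.0)
    counts = rng.poisson(lam * mult)
    return pd.Series(counts.astype(float), index=idx, name="value")


def simulate_occupancy(arrivals: pd.Series, los: LosModel, seed: int) -> pd.Series:
    """Infinite-server-queue occupancy implied by arrivals and stays.

    Each arriving patient gets a uniform within-hour arrival instant and an
    independent length of stay; occupancy at the top of hour ``t`` counts
    patients with ``arrival <= t < departure``.  Integer, non-negative,
    and lagging the arrival cycle through the stay carry-over.
    """
    rng = np.random.default_rng(seed)
    n_hours = len(arrivals)
    counts = arrivals.to_numpy(dtype=int)
    total = int(counts.sum())
    if n_hours == 0:
        return pd.Series(dtype=float, index=arrivals.index, name="value")
    # continuous arrival instants, in hours since the series start
    hour_idx = np.repeat(np.arange(n_hours), counts)
    t_arr = hour_idx + rng.uniform(0.0, 1.0, size=total)
    t_dep = t_arr + los.sample(total, rng)
    # occupancy at integer hours u: present iff ceil(t_arr) <= u < ceil(t_dep)
    first = np.ceil(t_arr).astype(np.int64)
    last = np.ceil(t_dep).astype(np.int64)  # exclusive
    delta = np.zeros(n_hours + 1, dtype=np.int64)
    np.add.at(delta, np.minimum(first, n_hours), 1)
    np.add.at(delta, np.minimum(last, n_hours), -1)
    occ = np.cumsum(delta[:-1])
    return pd.Series(occ.astype(float), index=arrivals.index, name="value")


def simulate_ed(n_days: int, seed: int, profile: DiurnalProfile | None = None,
                surge: SurgeModel | None = None, los: LosModel | None = None,
                start: str = DEFAULT_START,
                lead_in_days: int = 2) -> tuple[pd.Series, pd.Series]:
    """Generate consistent (arrivals, occupancy) series for ``n_days``.

    A lead-in period is simulated before the requested range and discarded
    so that occupancy at the start already carries realistic stay
    carry-over rather than an empty department.
    """
    if profile is None or surge is None or los is None:
        dp, ds, dl = default_profile()
        profile = profile or dp
        surge = surge or ds
        los = los or dl
    lead_start = pd.Timestamp(start) - pd.Timedelta(days=lead_in_days)
    arr = simulate_arrivals(profile, surge, n_days + lead_in_days, seed,
                            start=str(lead_start))
    occ = simulate_occupancy(arr, los, seed=seed + 1)
    keep = arr.index >= pd.Timestamp(start)
    return arr[keep], occ[keep]


def inject_gaps(obj, gap_fraction: float, seed: int, block_share: float = 0.7):
    """Remove hours (series) or origins (prediction store) to emulate downtime.

    A contiguous block accounts for ``block_share`` of the missing mass
    (credential-outage mode); the remainder is sporadic single hours
    (memory-issue mode).  Returns a gapped copy.
    """
    if not 0.0 <= gap_fraction <= 0.5:
        raise ValueError("gap fraction must be in [0, 0.5]")
    if hasattr(obj, "df"):  # prediction store
        from .harness import PredictionStore
        origins = pd.DatetimeIndex(sorted(obj.df["origin"].unique()))
        drop = _pick_gap_hours(origins, gap_fraction, seed, block_share)
        return PredictionStore(obj.df[~obj.df["origin"].isin(drop)].copy())
    series = obj
    drop = _pick_gap_hours(series.index, gap_fraction, seed, block_share)
    return series[~series.index.isin(drop)]


def _pick_gap_hours(idx: pd.DatetimeIndex, gap_fraction: float, seed: int,
                    block_share: float) -> pd.DatetimeIndex:
    n = len(idx)
    n_missing = int(round(n * gap_fraction))
    if n_missing == 0:
        return pd.DatetimeIndex([])
    rng = np.random.default_rng(seed)
    n_block = int(round(n_missing * block_share))
    start = int(rng.integers(0, max(n - n_block, 1)))
    block = set(range(start, min(start + n_block, n)))
    remaining = np.setdiff1d(np.arange(n), np.fromiter(block, dtype=int))
    n_sporadic = min(n_missing - len(block), len(remaining))
    sporadic = rng.choice(remaining, size=n_sporadic, replace=False)
    chosen = np.sort(np.concatenate([np.fromiter(block, dtype=int), sporadic]))
    return idx[chosen]
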