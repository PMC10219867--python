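"""Holt-Winters seasonal exponential smoothing for hourly ED series.

The three forecaster variants deployed in the early-warning system:

* ``additive``        — additive trend + additive seasonality (AHWM)
* ``multiplicative``  — additive trend + multiplicative seasonality (MHWM)
* ``damped``          — damped additive trend + additive seasonality (HWDM)

Usage follows the Model/Results convention: build a :class:`HoltWinters`
model from an hourly series, call :meth:`HoltWinters.fit` (maximum
likelihood over the smoothing weights) or :meth:`HoltWinters.filter`
(fixed parameters) to obtain a :class:`HoltWintersResults`, then
:meth:`HoltWintersResults.forecast` for multi-step point forecasts.

Parameters are the classical smoothing weights: level ``alpha``, trend
``beta``, seasonal ``gamma`` (all in [0, 1]) and, for the damped variant,
the damping factor ``phi`` in [0.8, 0.98].  With Gaussian one-step errors,
maximizing the likelihood is equivalent to minimizing the sum of squared
one-step residuals, which is what the optimizer does.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _smoothers
from .series import HOUR, validate_hourly

VARIANTS = ("additive", "multiplicative", "damped")

#: canonical model identifiers used in prediction stores / report tables
MODEL_IDS = {"additive": "AHWM", "multiplicative": "MHWM", "damped": "HWDM"}
VARIANT_OF_ID = {v: k for k, v in MODEL_IDS.items()}

PHI_BOUNDS = (0.8, 0.98)

# fixed multi-start grid for the bounded SSE optimization (alpha, beta, gamma)
_STARTS = (
    (0.3, 0.10, 0.10),
    (0.5, 0.05, 0.30),
    (0.1, 0.01, 0.05),
    (0.7, 0.20, 0.20),
    (0.2, 0.02, 0.60),
)


class InsufficientHistoryError(ValueError):
    """Training series shorter than the two seasonal cycles needed to initialize."""


class FittingError(RuntimeError):
    """All optimizer starts failed; carries best-so-far diagnostics."""


@dataclass(frozen=True)
class EtsSpec:
    """Model variant and structural settings."""

    variant: str = "additive"
    seasonal_periods: int = 24
    trend: bool = True

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.seasonal_periods < 2:
            raise ValueError("seasonal_periods must be >= 2")

    @property
    def model_id(self) -> str:
        return MODEL_IDS[self.variant]

    @property
    def damped(self) -> bool:
        return self.variant == "damped"

    @property
    def seasonal(self) -> str:
        return "mul" if self.variant == "multiplicative" else "add"


@dataclass
class EtsParams:
    """Smoothing weights (classical parameterization) and residual variance."""

    alpha: float
    beta: float
    gamma: float
    phi: float = 1.0
    sigma2: float = float("nan")

    def validate(self, spec: EtsSpec) -> "EtsParams":
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if spec.damped and not PHI_BOUNDS[0] <= self.phi <= PHI_BOUNDS[1]:
            raise ValueError(f"phi={self.phi} outside {PHI_BOUNDS}")
        return self


@dataclass
class EtsState:
    """Level, trend slope, and the most recent m seasonal indices."""

    level: float
    trend: float
    season: np.ndarray = field(repr=False)

    def copy(self) -> "EtsState":
        return EtsState(self.level, self.trend, self.season.copy())


@dataclass
class SmoothedTrajectory:
    """Per-step smoothing states and one-step residuals over a training run."""

    level: np.ndarray
    trend: np.ndarray
    season: np.ndarray  # length n + m; first m entries are the initial indices
    fitted: np.ndarray
    resid: np.ndarray

    @property
    def final_state(self) -> EtsState:
        n = len(self.level)
        m = len(self.season) - n
        return EtsState(self.level[-1], self.trend[-1], self.season[n : n + m].copy())


class HoltWinters:
    """Holt-Winters seasonal smoothing model for one hourly target series.

    Parameters
    ----------
    endog : pandas.Series or array-like
        Hourly training values.  A pandas Series must satisfy the hourly
        contract (see :mod:`edwarn.series`) and be gap-free; use
        :func:`edwarn.series.prepare_training` first if it is not.
    variant : str
        ``"additive"``, ``"multiplicative"`` or ``"damped"``.
    seasonal_periods : int
        Seasonal cycle length; 24 for the daily cycle on hourly data.
    trend : bool
        Include a trend component (fixed at zero when False).

    Notes
    -----
    The multiplicative variant requires strictly positive values; series
    containing zeros (overnight arrival counts) are shifted by a fixed
    offset of 0.5 for training and the offset is removed from forecasts.
    """

    ZERO_OFFSET = 0.5

    def __init__(self, endog, variant: str = "additive", seasonal_periods: int = 24,
                 trend: bool = True):
        self.spec = EtsSpec(variant, seasonal_periods, trend)
        if isinstance(endog, pd.Series):
            validate_hourly(endog)
            if len(endog) > 1 and (np.diff(endog.index.asi8) != HOUR.value).any():
                raise ValueError("training series has gaps; apply prepare_training first")
            self._index = endog.index
            y = endog.to_numpy(dtype=float)
        else:
            self._index = None
            y = np.asarray(endog, dtype=float)
        m = self.spec.seasonal_periods
        if len(y) < 2 * m:
            raise InsufficientHistoryError(
                f"need at least {2 * m} observations to initialize, got {len(y)}")
        self.offset = 0.0
        if self.spec.variant == "multiplicative" and y.min() <= 0.0:
            self.offset = self.ZERO_OFFSET
        self.endog = y
        self._y = y + self.offset

    @classmethod
    def from_series(cls, series: pd.Series, spec: EtsSpec) -> "HoltWinters":
        return cls(series, spec.variant, spec.seasonal_periods, spec.trend)

    @property
    def nobs(self) -> int:
        return len(self.endog)

    @property
    def train_end(self):
        return self._index[-1] if self._index is not None else self.nobs - 1

    # -- initialization ----------------------------------------------------

    def initialize_states(self) -> EtsState:
        """Heuristic seasonal-average initialization from the first two cycles.

        Level is the mean of the first cycle, trend the per-step difference
        between the second and first cycle means, and the seasonal indices
        are per-position deviations from each cycle's mean (differences for
        additive seasonality, normalized to sum to zero; ratios for
        multiplicative, normalized to average one).
        """
        m = self.spec.seasonal_periods
        y = self._y
        c1, c2 = y[:m], y[m : 2 * m]
        level = c1.mean()
        trend = (c2.mean() - c1.mean()) / m if self.spec.trend else 0.0
        if self.spec.seasonal == "add":
            dev = np.concatenate([c1 - c1.mean(), c2 - c2.mean()])
            season = dev.reshape(2, m).mean(axis=0)
            season = season - season.mean()
        else:
            if c1.mean() <= 0 or c2.mean() <= 0:
                raise ValueError("multiplicative initialization needs positive cycle means")
            ratio = np.concatenate([c1 / c1.mean(), c2 / c2.mean()])
            season = ratio.reshape(2, m).mean(axis=0)
            season = season / season.mean()
        return EtsState(float(level), float(trend), season)

    # -- smoothing ---------------------------------------------------------

    def smooth(self, params: EtsParams, init: EtsState | None = None) -> SmoothedTrajectory:
        """Run the smoothing recursions at fixed parameters.

        Returns the per-step state trajectory and one-step residuals
        ``e_t = y_t - yhat_{t|t-1}`` (on the offset-adjusted scale).
        """
        params.validate(self.spec)
        if init is None:
            init = self.initialize_states()
        phi = params.phi if self.spec.damped else 1.0
        beta = params.beta if self.spec.trend else 0.0
        kern = (_smoothers.smooth_multiplicative if self.spec.seasonal == "mul"
                else _smoothers.smooth_additive)
        level, trend, season, fitted = kern(
            self._y, params.alpha, beta, params.gamma, phi,
            init.level, init.trend, np.asarray(init.season, dtype=float))
        if not np.isfinite(fitted).all():
            raise FloatingPointError(
                "multiplicative recursion hit a zero level/seasonal state")
        return SmoothedTrajectory(level, trend, season, fitted, self._y - fitted)

    def _sse(self, x: np.ndarray, init: EtsState) -> float:
        alpha, beta, gamma = x[0], x[1], x[2]
        phi = x[3] if self.spec.damped else 1.0
        if not self.spec.trend:
            beta = 0.0
        kern = (_smoothers.sse_multiplicative if self.spec.seasonal == "mul"
                else _smoothers.sse_additive)
        sse = kern(self._y, alpha, beta, gamma, phi,
                   init.level, init.trend, init.season)
        return sse if np.isfinite(sse) else 1e12

    # -- estimation --------------------------------------------------------

    def fit(self, n_starts: int = 5, seed: int = 0, maxiter: int = 200) -> "HoltWintersResults":
        """Estimate smoothing weights by maximum likelihood.

        Gaussian one-step-error likelihood, equivalent to minimizing the
        residual sum of squares, over the bounded parameter box via
        L-BFGS-B from ``n_starts`` starting points (a fixed grid, extended
        by seeded random draws beyond five starts).
        """
        init = self.initialize_states()
        bounds = [(0.0, 1.0)] * 3
        starts = [np.array(s) for s in _STARTS[:n_starts]]
        if n_starts > len(_STARTS):
            rng = np.random.default_rng(seed)
            starts += [rng.uniform(0.01, 0.99, size=3) for _ in range(n_starts - len(_STARTS))]
        if self.spec.damped:
            bounds.append(PHI_BOUNDS)
            starts = [np.append(s, 0.9 if i % 2 == 0 else 0.96) for i, s in enumerate(starts)]
        best = None
        failures = []
        for x0 in starts:
            try:
                res = minimize(self._sse, x0, args=(init,), method="L-BFGS-B",
                               bounds=bounds, options={"maxiter": maxiter})
            except Exception as exc:  # pragma: no cover - optimizer crash path
                failures.append((x0, exc))
                continue
            if not np.isfinite(res.fun):
                failures.append((x0, res.message))
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise FittingError(f"all {len(starts)} optimizer starts failed: {failures}")
        x = np.clip(best.x, [b[0] for b in bounds], [b[1] for b in bounds])
        params = EtsParams(alpha=float(x[0]),
                           beta=float(x[1]) if self.spec.trend else 0.0,
                           gamma=float(x[2]),
                           phi=float(x[3]) if self.spec.damped else 1.0)
        return self.filter(params, init=init)

    def filter(self, params: EtsParams, init: EtsState | None = None) -> "HoltWintersResults":
        """Build a results object at fixed parameters (no optimization)."""
        traj = self.smooth(params, init=init)
        n = self.nobs
        sigma2 = float(traj.resid @ traj.resid) / n
        loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0) if sigma2 > 0 else np.inf
        return HoltWintersResults(self, replace(params, sigma2=sigma2), traj, float(loglik))


class HoltWintersResults:
    """Fitted Holt-Winters model: estimates, final state, and forecasts."""

    def __init__(self, model: HoltWinters, params: EtsParams, traj: SmoothedTrajectory,
                 loglik: float):
        self.model = model
        self.spec = model.spec
        self.params = params
        self.trajectory = traj
        self.final_state = traj.final_state
        self.loglik = loglik
        self.nobs = model.nobs

    @property
    def sigma2(self) -> float:
        return self.params.sigma2

    @property
    def sse(self) -> float:
        return self.sigma2 * self.nobs

    @property
    def fittedvalues(self):
        """One-step-ahead in-sample predictions on the original scale."""
        f = self.trajectory.fitted - self.model.offset
        if self.model._index is not None:
            return pd.Series(f, index=self.model._index)
        return f

    @property
    def resid(self):
        r = self.model.endog - (self.trajectory.fitted - self.model.offset)
        if self.model._index is not None:
            return pd.Series(r, index=self.model._index)
        return r

    @property
    def train_end(self):
        return self.model.train_end

    def forecast(self, h: int = 24, floor: bool = True):
        """Point forecasts for horizons 1..h from the final smoothed state.

        Additive: ``l + k*b + s``; damped: ``l + (phi + ... + phi^k)*b + s``;
        multiplicative: ``(l + k*b) * s`` — with ``s`` the most recent
        seasonal index for the matching position.  Forecasts of counts are
        floored at zero (no integer rounding: downstream AUC evaluation
        uses them as continuous scores).
        """
        if h < 1:
            raise ValueError("horizon must be >= 1")
        st = self.final_state
        m = self.spec.seasonal_periods
        k = np.arange(1, h + 1)
        if self.spec.damped:
            damp = np.cumsum(self.params.phi ** k)
        else:
            damp = k.astype(float)
        seas = st.season[(k - 1) % m]
        base = st.level + damp * st.trend
        f = base * seas if self.spec.seasonal == "mul" else base + seas
        f = f - self.model.offset
        if floor:
            f = np.maximum(f, 0.0)
        if self.model._index is not None:
            idx = pd.date_range(self.model._index[-1] + HOUR, periods=h, freq="h")
            return pd.Series(f, index=idx)
        return f

    def summary(self) -> str:
        """Plain-text estimation summary."""
        p = self.params
        lines = [
            "Holt-Winters Smoothing Results",
            "=" * 46,
            f"{'variant:':<22}{self.spec.variant} ({self.spec.model_id})",
            f"{'seasonal period:':<22}{self.spec.seasonal_periods}",
            f"{'nobs:':<22}{self.nobs}",
            f"{'train end:':<22}{self.train_end}",
            f"{'log-likelihood:':<22}{self.loglik:.2f}",
            "-" * 46,
            f"{'alpha (level):':<22}{p.alpha:.4f}",
            f"{'beta (trend):':<22}{p.beta:.4f}",
            f"{'gamma (seasonal):':<22}{p.gamma:.4f}",
        ]
        if self.spec.damped:
            lines.append(f"{'phi (damping):':<22}{p.phi:.4f}")
        lines += [
            f"{'sigma2 (resid var):':<22}{p.sigma2:.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<HoltWintersResults {self.spec.model_id} nobs={self.nobs} "
                f"alpha={self.params.alpha:.3f} gamma={self.params.gamma:.3f}>")
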