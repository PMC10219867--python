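"""Compiled Holt-Winters smoothing kernels.

Classical (Hyndman-parameterized) seasonal exponential-smoothing recursions
with additive or multiplicative seasonality and a (possibly damped) additive
trend.  phi = 1 gives the undamped recursions.

Additive seasonality::

    yhat_t = l_{t-1} + phi*b_{t-1} + s_{t-m}
    l_t    = alpha*(y_t - s_{t-m})            + (1-alpha)*(l_{t-1} + phi*b_{t-1})
    b_t    = beta*(l_t - l_{t-1})             + (1-beta)*phi*b_{t-1}
    s_t    = gamma*(y_t - l_{t-1} - phi*b_{t-1}) + (1-gamma)*s_{t-m}

Multiplicative seasonality replaces subtraction/addition of the seasonal
index by division/multiplication.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def smooth_additive(y, alpha, beta, gamma, phi, l0, b0, s0):
    n = y.shape[0]
    m = s0.shape[0]
    level = np.empty(n)
    trend = np.empty(n)
    season = np.empty(n + m)
    fitted = np.empty(n)
    season[:m] = s0
    lp = l0
    bp = b0
    for t in range(n):
        sprev = season[t]
        base = lp + phi * bp
        fitted[t] = base + sprev
        lt = alpha * (y[t] - sprev) + (1.0 - alpha) * base
        bt = beta * (lt - lp) + (1.0 - beta) * phi * bp
        season[t + m] = gamma * (y[t] - base) + (1.0 - gamma) * sprev
        level[t] = lt
        trend[t] = bt
        lp = lt
        bp = bt
    return level, trend, season, fitted


@njit(cache=True)
def smooth_multiplicative(y, alpha, beta, gamma, phi, l0, b0, s0):
    n = y.shape[0]
    m = s0.shape[0]
    level = np.empty(n)
    trend = np.empty(n)
    season = np.empty(n + m)
    fitted = np.empty(n)
    season[:m] = s0
    lp = l0
    bp = b0
    for t in range(n):
        sprev = season[t]
        base = lp + phi * bp
        if sprev == 0.0 or base == 0.0:
            # signal a numerical-domain failure to the caller via NaN
            fitted[t:] = np.nan
            level[t:] = np.nan
            trend[t:] = np.nan
            season[t + m :] = np.nan
            return level, trend, season, fitted
        fitted[t] = base * sprev
        lt = alpha * (y[t] / sprev) + (1.0 - alpha) * base
        bt = beta * (lt - lp) + (1.0 - beta) * phi * bp
        season[t + m] = gamma * (y[t] / base) + (1.0 - gamma) * sprev
        level[t] = lt
        trend[t] = bt
        lp = lt
        bp = bt
    return level, trend, season, fitted


@njit(cache=True)
def sse_additive(y, alpha, beta, gamma, phi, l0, b0, s0):
    """Sum of squared one-step residuals (allocation-free objective)."""
    n = y.shape[0]
    m = s0.shape[0]
    season = np.empty(n + m)
    season[:m] = s0
    lp = l0
    bp = b0
    sse = 0.0
    for t in range(n):
        sprev = season[t]
        base = lp + phi * bp
        e = y[t] - (base + sprev)
        sse += e * e
        lt = alpha * (y[t] - sprev) + (1.0 - alpha) * base
        bp = beta * (lt - lp) + (1.0 - beta) * phi * bp
        season[t + m] = gamma * (y[t] - base) + (1.0 - gamma) * sprev
        lp = lt
    return sse


@njit(cache=True)
def sse_multiplicative(y, alpha, beta, gamma, phi, l0, b0, s0):
    n = y.shape[0]
    m = s0.shape[0]
    season = np.empty(n + m)
    season[:m] = s0
    lp = l0
    bp = b0
    sse = 0.0
    for t in range(n):
        sprev = season[t]
        base = lp + phi * bp
        if sprev == 0.0 or base == 0.0:
            return np.inf
        e = y[t] - base * sprev
        sse += e * e
        lt = alpha * (y[t] / sprev) + (1.0 - alpha) * base
        bp = beta * (lt - lp) + (1.0 - beta) * phi * bp
        season[t + m] = gamma * (y[t] / base) + (1.0 - gamma) * sprev
        lp = lt
    return sse
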