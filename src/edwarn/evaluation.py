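"""Binary and continuous evaluation of prospective crowding forecasts.

Four reporting phases:

1. aggregated continuous accuracy (MAE / MSE / RMSE over all horizons),
2. performance per horizon (PPH) — AUC of hourly crowding prediction for
   each horizon 1..24, aggregated over origins,
3. performance per origin (PPO) — AUC of "any crowding within the next
   24 h" for each origin hour-of-day, and
4. the origin-hour x horizon AUC matrix.

AUC is the rank-based (Mann-Whitney) statistic with midrank tie handling.
Because crowded hours are rare, noncrowded instances are randomly
downsampled to class balance before each AUC; confidence intervals come
from a percentile bootstrap over (score, label) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .crowding import CrowdingScheme

DEFAULT_BOOTSTRAP = 250


class UndefinedAUCError(ValueError):
    """AUC requested on a single-class pair set."""


@dataclass(frozen=True)
class AucResult:
    """AUC point estimate with bootstrap CI and class counts."""

    auc: float
    ci_lo: float
    ci_hi: float
    n_pos: int
    n_neg: int
    n_boot: int = DEFAULT_BOOTSTRAP


def _as_pairs(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    keep = np.isfinite(scores) & np.isfinite(labels)
    return scores[keep], labels[keep].astype(int)


def auc(scores, labels) -> float:
    """Mann-Whitney AUC with midrank ties: P(s_pos > s_neg) + 0.5 P(tie).

    Raises :class:`UndefinedAUCError` when only one class is present —
    an undefined AUC is a signal, never silently 0 or 0.5.
    """
    scores, labels = _as_pairs(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError(f"need both classes (n_pos={n_pos}, n_neg={n_neg})")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def downsample_balance(scores, labels, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Downsample the majority class without replacement to class balance.

    All minority-class pairs are kept; the draw is deterministic given the
    seed.  (Normally the noncrowded class is the majority; if positives
    ever outnumber negatives the downsampling applies to them instead.)
    """
    scores, labels = _as_pairs(scores, labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedAUCError("both classes required for balancing")
    rng = np.random.default_rng(seed)
    if len(neg) >= len(pos):
        neg = rng.choice(neg, size=len(pos), replace=False)
    else:
        pos = rng.choice(pos, size=len(neg), replace=False)
    keep = np.sort(np.concatenate([pos, neg]))
    return scores[keep], labels[keep]


def bootstrap_ci(scores, labels, n_boot: int = DEFAULT_BOOTSTRAP,
                 level: float = 0.95, seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC.

    Pairs are resampled jointly with replacement; a resample that loses one
    of the classes is redrawn.
    """
    scores, labels = _as_pairs(scores, labels)
    n = len(scores)
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if 0 < lab.sum() < n:
                break
        stats[b] = auc(scores[idx], lab)
    alpha = 1.0 - level
    lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def balanced_auc(scores, labels, seed: int, n_boot: int = DEFAULT_BOOTSTRAP,
                 n_draws: int = 1) -> AucResult:
    """Class-balanced AUC with bootstrap CI (one seeded downsampling draw
    by default; ``n_draws > 1`` averages the point estimate over repeated
    draws to reduce draw noise, with the CI from the first draw)."""
    aucs = []
    first = None
    for d in range(n_draws):
        s, l = downsample_balance(scores, labels, seed + d)
        if first is None:
            first = (s, l)
        aucs.append(auc(s, l))
    s, l = first
    lo, hi = bootstrap_ci(s, l, n_boot=n_boot, seed=seed)
    n_pos = int(l.sum())
    return AucResult(float(np.mean(aucs)), lo, hi, n_pos, len(l) - n_pos, n_boot)


# -- phase 1: continuous accuracy -----------------------------------------

def continuous_metrics(rows: pd.DataFrame) -> pd.DataFrame:
    """MAE / MSE / RMSE per model x target, aggregated over all horizons."""
    if len(rows) == 0:
        raise ValueError("no evaluation rows")
    err = rows["yhat"].to_numpy(dtype=float) - rows["y_actual"].to_numpy(dtype=float)
    g = rows.assign(abs_err=np.abs(err), sq_err=err ** 2).groupby(
        ["target", "model_id"], as_index=False).agg(
        mae=("abs_err", "mean"), mse=("sq_err", "mean"), n=("abs_err", "size"))
    g["rmse"] = np.sqrt(g["mse"])
    return g[["target", "model_id", "mae", "mse", "rmse", "n"]]


# -- phase 2: performance per horizon --------------------------------------

def pph(rows: pd.DataFrame, target: str = "occupancy", seed: int = 0,
        n_boot: int = DEFAULT_BOOTSTRAP, n_draws: int = 1) -> pd.DataFrame:
    """Per-horizon balanced AUC of hourly crowding prediction.

    For each model and horizon h, the pairs are (forecast for origin+h,
    crowding label at origin+h).  Horizons without both classes are
    reported with missing AUC.
    """
    sub = rows[(rows["target"] == target) & rows["hour_label"].notna()]
    out = []
    for model_id, g in sub.groupby("model_id"):
        for h in range(1, 25):
            gh = g[g["horizon"] == h]
            rec = {"model_id": model_id, "horizon": h}
            try:
                r = balanced_auc(gh["yhat"], gh["hour_label"],
                                 seed=_strata_seed(seed, 0, h), n_boot=n_boot,
                                 n_draws=n_draws)
                rec.update(auc=r.auc, ci_lo=r.ci_lo, ci_hi=r.ci_hi,
                           n_pos=r.n_pos, n_neg=r.n_neg)
            except UndefinedAUCError:
                rec.update(auc=np.nan, ci_lo=np.nan, ci_hi=np.nan, n_pos=0, n_neg=0)
            out.append(rec)
    return pd.DataFrame(out)


# -- phase 3: performance per origin ---------------------------------------

def window_rows(rows: pd.DataFrame, scheme: CrowdingScheme,
                target: str = "occupancy") -> pd.DataFrame:
    """Collapse per-horizon rows into one row per (origin, model).

    Score is the maximum of the 24 point forecasts (the predicted daily
    peak); the label is 1 when any observed hour in the window is crowded,
    0 when all 24 hours were observed uncrowded, and missing otherwise.
    Origins with missing label or an incomplete forecast set are dropped.
    """
    sub = rows[rows["target"] == target]
    g = sub.groupby(["model_id", "origin"], as_index=False).agg(
        score=("yhat", "max"),
        n_h=("horizon", "nunique"),
        n_crowd=("hour_label", lambda s: np.nansum(s.to_numpy())),
        n_lab=("hour_label", "count"),
        origin_hour=("origin_hour", "first"))
    W = scheme.window
    label = np.where(g["n_crowd"] > 0, 1.0, np.where(g["n_lab"] >= W, 0.0, np.nan))
    g["label"] = label
    g = g[g["label"].notna()]
    return g[["model_id", "origin", "origin_hour", "score", "label"]]


def ppo(rows: pd.DataFrame, scheme: CrowdingScheme, seed: int = 0,
        target: str = "occupancy", n_boot: int = DEFAULT_BOOTSTRAP,
        n_draws: int = 1) -> pd.DataFrame:
    """Per-origin-hour balanced AUC of 24-hour-window crowding prediction."""
    wr = window_rows(rows, scheme, target)
    out = []
    for model_id, g in wr.groupby("model_id"):
        for o in range(24):
            go = g[g["origin_hour"] == o]
            rec = {"model_id": model_id, "origin_hour": o}
            try:
                r = balanced_auc(go["score"], go["label"],
                                 seed=_strata_seed(seed, 1, o), n_boot=n_boot,
                                 n_draws=n_draws)
                rec.update(auc=r.auc, ci_lo=r.ci_lo, ci_hi=r.ci_hi,
                           n_pos=r.n_pos, n_neg=r.n_neg)
            except UndefinedAUCError:
                rec.update(auc=np.nan, ci_lo=np.nan, ci_hi=np.nan, n_pos=0, n_neg=0)
            out.append(rec)
    return pd.DataFrame(out)


# -- phase 4: AUC matrix ----------------------------------------------------

def auc_matrix(rows: pd.DataFrame, model_id: str,
               target: str = "occupancy") -> pd.DataFrame:
    """24x24 grid of AUCs by (origin hour-of-day, horizon).

    Cell (o, h) scores the pairs restricted to that origin hour and
    horizon; cells whose restricted sample has a single class (e.g. no
    recorded crowding event) are missing.
    """
    sub = rows[(rows["target"] == target) & (rows["model_id"] == model_id)
               & rows["hour_label"].notna()]
    mat = np.full((24, 24), np.nan)
    for (o, h), g in sub.groupby(["origin_hour", "horizon"]):
        try:
            mat[int(o), int(h) - 1] = auc(g["yhat"], g["hour_label"])
        except UndefinedAUCError:
            pass
    return pd.DataFrame(mat, index=pd.RangeIndex(24, name="origin_hour"),
                        columns=[f"t+{h}" for h in range(1, 25)])


# -- single-threshold binary metrics ----------------------------------------

def binary_metrics(scores, labels, threshold: float) -> dict:
    """Confusion-matrix metrics at ``score >= threshold => predict crowded``.

    Ratios with zero denominators are reported as NaN (missing), not 0.
    """
    scores, labels = _as_pairs(scores, labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    prec = tp / (tp + fp) if tp + fp else np.nan
    f1 = (2 * prec * sens / (prec + sens)
          if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0 else np.nan)
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "sensitivity": sens, "specificity": spec, "precision": prec, "f1": f1}


def _strata_seed(seed: int, phase: int, stratum: int) -> int:
    """Distinct deterministic sub-seed per evaluation stratum (< 2**31)."""
    return (seed * 1000 + phase * 100 + stratum) % (2 ** 31 - 1)
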