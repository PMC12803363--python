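"""Pooling across imputations and accuracy reporting.

Predictions made on each of the m completed datasets are combined with
Rubin's rules: pooled point estimate Q̄ (mean over m), within-variance W
(mean of per-dataset variances), between-variance B (sample variance of
the m estimates), total T = W + (1 + 1/m)·B, and small-sample degrees of
freedom for the interval.  RMSE is computed within each imputation and
pooled the same way, with the within-variance of an RMSE obtained by the
delta method from the spread of squared errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PREDICTION_KEYS = ["learner", "spec", "horizon", "patient_id", "t_index"]


def rubin_combine(estimates: np.ndarray, within: np.ndarray) -> dict[str, float]:
    """Rubin's rules for m estimates with within-variances.

    Returns Q̄, W, B, T, df and a 95% interval (Student-t with Rubin df;
    normal when df > 100 or B = 0).
    """
    estimates = np.asarray(estimates, float)
    within = np.asarray(within, float)
    m = estimates.size
    if m < 1 or within.size != m:
        raise ValueError("need m >= 1 estimates with matching within-variances")
    qbar = float(estimates.mean())
    w = float(within.mean())
    b = float(estimates.var(ddof=1)) if m > 1 else 0.0
    t_var = w + (1 + 1 / m) * b if m > 1 else w
    if b > 0 and m > 1:
        df = (m - 1) * (1 + w / ((1 + 1 / m) * b)) ** 2
    else:
        df = math.inf
    half = _half_width(t_var, df)
    return {
        "qbar": qbar,
        "within": w,
        "between": b,
        "total": t_var,
        "df": df,
        "ci_low": qbar - half,
        "ci_high": qbar + half,
    }


def _half_width(total_var: float, df: float, level: float = 0.95) -> float:
    if total_var <= 0:
        return 0.0
    alpha = 1 - level
    if math.isinf(df) or df > 100:
        crit = float(stats.norm.ppf(1 - alpha / 2))
    else:
        crit = float(stats.t.ppf(1 - alpha / 2, df))
    return crit * math.sqrt(total_var)


def pool_predictions(predictions: pd.DataFrame) -> pd.DataFrame:
    """Rubin-pool per-imputation predictions into one row per test cell.

    Expects the long prediction table with columns imputation_id, learner,
    spec, horizon, patient_id, t_index, prediction, within_variance (and
    target, carried through).  All m imputations must cover the same cells.
    """
    counts = predictions.groupby(PREDICTION_KEYS)["imputation_id"].nunique()
    m = predictions["imputation_id"].nunique()
    if (counts != m).any():
        bad = counts[counts != m].index[:3].tolist()
        raise ValueError(f"coverage mismatch across imputations, e.g. {bad}")
    rows = []
    for key, grp in predictions.groupby(PREDICTION_KEYS, sort=True):
        pooled = rubin_combine(
            grp["prediction"].to_numpy(), grp["within_variance"].to_numpy()
        )
        rec = dict(zip(PREDICTION_KEYS, key))
        rec.update(
            qbar=pooled["qbar"],
            within=pooled["within"],
            between=pooled["between"],
            total=pooled["total"],
            df=pooled["df"],
            ci_low=pooled["ci_low"],
            ci_high=pooled["ci_high"],
        )
        if "target" in grp:
            rec["target"] = float(grp["target"].iloc[0])
        rows.append(rec)
    return pd.DataFrame(rows)


def _rmse_with_delta_variance(errors: np.ndarray) -> tuple[float, float]:
    """RMSE and its delta-method variance: Var(sq errors) / (4 n MSE)."""
    sq = errors**2
    n = sq.size
    mse = float(sq.mean())
    rmse = math.sqrt(mse)
    if mse == 0 or n < 2:
        return rmse, 0.0
    return rmse, float(sq.var(ddof=1)) / (4 * n * mse)


def compute_rmse(
    predictions: pd.DataFrame, min_rows_per_t: int = 10
) -> pd.DataFrame:
    """Pooled RMSE with SE per (learner, spec, horizon) and per time point.

    RMSE is computed within each imputation and Rubin-combined; overall rows
    have ``t_index`` = -1.  Per-time-point cells with fewer than
    ``min_rows_per_t`` test rows are flagged ``suppressed`` and carry NaN.
    """
    if predictions.empty:
        raise ValueError("empty prediction table")
    rows = []
    for (learner, spec, horizon), grp in predictions.groupby(["learner", "spec", "horizon"]):
        rows.append(
            _pooled_rmse_row(grp, learner, spec, horizon, t_index=-1, suppressed=False)
        )
        for t, sub in grp.groupby("t_index"):
            n_rows = len(sub) // sub["imputation_id"].nunique()
            if n_rows < min_rows_per_t:
                rows.append(
                    {
                        "learner": learner, "spec": spec, "horizon": horizon,
                        "t_index": int(t), "rmse": math.nan, "se": math.nan,
                        "n_rows": n_rows, "m": sub["imputation_id"].nunique(),
                        "suppressed": True,
                    }
                )
            else:
                rows.append(
                    _pooled_rmse_row(sub, learner, spec, horizon, int(t), False)
                )
    return pd.DataFrame(rows)


def _pooled_rmse_row(
    grp: pd.DataFrame, learner: str, spec: str, horizon: int, t_index: int, suppressed: bool
) -> dict:
    per_imp = []
    within = []
    n_rows = 0
    for _, sub in grp.groupby("imputation_id"):
        err = sub["prediction"].to_numpy(float) - sub["target"].to_numpy(float)
        rmse_m, var_m = _rmse_with_delta_variance(err)
        per_imp.append(rmse_m)
        within.append(var_m)
        n_rows = err.size
    pooled = rubin_combine(np.array(per_imp), np.array(within))
    return {
        "learner": learner,
        "spec": spec,
        "horizon": horizon,
        "t_index": t_index,
        "rmse": pooled["qbar"],
        "se": math.sqrt(pooled["total"]),
        "n_rows": n_rows,
        "m": len(per_imp),
        "suppressed": suppressed,
    }


def evaluation_summary(rmse_report: pd.DataFrame, target_sd: float) -> dict:
    """Machine-readable summary: RMSE/SD ratios and ordering flags."""
    overall = rmse_report[rmse_report["t_index"] == -1]
    cells = {}
    for r in overall.itertuples():
        key = f"{r.learner}/{r.spec}/h{r.horizon}"
        cells[key] = {
            "rmse": float(r.rmse),
            "se": float(r.se),
            "rmse_over_sd": float(r.rmse) / target_sd if target_sd > 0 else math.nan,
            "n_rows": int(r.n_rows),
        }
    orderings = {}
    for learner in overall["learner"].unique():
        sub = overall[overall["learner"] == learner].set_index(["spec", "horizon"])["rmse"]
        for h in sorted({i[1] for i in sub.index}):
            if ("FULL", h) in sub.index and ("SKIPPED", h) in sub.index:
                orderings[f"{learner}/h{h}/full_le_skipped"] = bool(
                    sub[("FULL", h)] <= sub[("SKIPPED", h)]
                )
        for spec in sorted({i[0] for i in sub.index}):
            if (spec, 1) in sub.index and (spec, 2) in sub.index:
                orderings[f"{learner}/{spec}/h1_le_h2"] = bool(sub[(spec, 1)] <= sub[(spec, 2)])
    return {"target_sd": target_sd, "cells": cells, "orderings": orderings}
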