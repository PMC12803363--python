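"""Local, windowed, iterative multiple imputation of aligned biomarker grids.

Missing cells inside each patient's follow-up window are filled by an
interval-specific linear model: the value at index ``t`` is regressed, over
patients observed at ``t``, on the de-meaned values at ``t-2, t-1, t+1,
t+2`` plus baseline covariates.  Imputations are drawn as the linear
predictor plus Gaussian noise at the fitted residual SD (or by predictive
mean matching), sweeping forward across intervals and iterating so that
each cycle refines draws made in the previous one.  After a burn-in phase
the state is branched into ``m`` completed datasets whose spread carries
the imputation uncertainty.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WINDOW_OFFSETS = (-2, -1, 1, 2)
WINDOW_NAMES = ("lag2", "lag1", "lead1", "lead2")

SEX_LEVELS = ["F", "M"]
TREATMENT_LEVELS = ["imatinib", "dasatinib", "nilotinib"]

DEFAULT_BURNIN = 15
DEFAULT_M = 10


def build_covariate_design(
    covariates: pd.DataFrame, patient_ids: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix for baseline covariates, one row per patient.

    Categorical variables are one-hot encoded against fixed level
    dictionaries with the first level as reference.  Missing BMI is filled
    with the cohort mean and flagged with an indicator column.
    """
    cov = covariates.set_index(covariates["patient_id"].astype(str))
    missing = [p for p in patient_ids if p not in cov.index]
    if missing:
        raise KeyError(f"covariates missing for patients: {missing[:5]}")
    cov = cov.loc[patient_ids]

    age = cov["age_at_dx"].to_numpy(float)
    if np.any(~np.isfinite(age)) or np.any(age <= 18):
        raise ValueError("age_at_dx must be finite and > 18 for every patient")

    bmi = cov["bmi"].to_numpy(float)
    bmi_missing = ~np.isfinite(bmi)
    cols = [age]
    names = ["age_at_dx"]
    if bmi_missing.any():
        bmi = np.where(bmi_missing, np.nanmean(bmi), bmi)
        cols += [bmi, bmi_missing.astype(float)]
        names += ["bmi", "bmi_missing"]
    else:
        cols.append(bmi)
        names.append("bmi")

    for col, levels in (("sex", SEX_LEVELS), ("first_line_treatment", TREATMENT_LEVELS)):
        vals = cov[col].astype(str)
        unknown = set(vals) - set(levels)
        if unknown:
            raise ValueError(f"unknown {col} level(s): {sorted(unknown)}")
        for level in levels[1:]:
            cols.append((vals == level).to_numpy(float))
            names.append(f"{col}_{level}")
    return np.column_stack(cols), names


@dataclass
class LocalModelFit:
    """OLS fit of the interval-t model; flagged degenerate when unfittable."""

    t_index: int
    intercept: float
    beta: np.ndarray  # window coefficients, order = WINDOW_NAMES
    gamma: np.ndarray  # covariate coefficients
    residual_sd: float
    n_fit: int
    se: np.ndarray  # per coefficient incl. intercept
    degenerate: bool = False

    @property
    def coef(self) -> np.ndarray:
        return np.concatenate([[self.intercept], self.beta, self.gamma])

    def coef_names(self, covariate_names: list[str]) -> list[str]:
        return ["intercept", *WINDOW_NAMES, *covariate_names]

    def linear_predictor(self, z: np.ndarray, x: np.ndarray) -> np.ndarray:
        return self.intercept + z @ self.beta + x @ self.gamma


def fit_local_model(
    y: np.ndarray, z: np.ndarray, x: np.ndarray, t_index: int = -1
) -> LocalModelFit:
    """OLS of y on [1 | z | x]; residual SD uses denominator n - p - 1.

    ``z`` has the four window columns, ``x`` the covariate columns; rows are
    the patients observed at this interval.  Predictor columns that are
    constant over the fit rows (e.g. an indicator for a category absent at
    this interval) are excluded from the regression and get coefficient 0,
    SE NaN; residual collinearity after that exclusion flags the fit
    degenerate.
    """
    n = y.size
    full = np.column_stack([np.ones(n), z, x])
    n_total = full.shape[1]
    keep = np.ones(n_total, bool)
    if n > 0:
        spans = full.max(axis=0) - full.min(axis=0)
        keep[1:] = spans[1:] > 1e-12
    design = full[:, keep]
    n_params = design.shape[1]
    if n < n_params + 1:
        return _degenerate_fit(t_index, z.shape[1], x.shape[1], n)
    coef_k, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < n_params:
        return _degenerate_fit(t_index, z.shape[1], x.shape[1], n)
    resid = y - design @ coef_k
    dof = n - n_params
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(design.T @ design)
    se_k = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    coef = np.zeros(n_total)
    se = np.full(n_total, math.nan)
    coef[keep] = coef_k
    se[keep] = se_k
    return LocalModelFit(
        t_index=t_index,
        intercept=float(coef[0]),
        beta=coef[1 : 1 + z.shape[1]],
        gamma=coef[1 + z.shape[1] :],
        residual_sd=math.sqrt(max(sigma2, 0.0)),
        n_fit=n,
        se=se,
    )


def _degenerate_fit(t: int, nz: int, nx: int, n: int) -> LocalModelFit:
    return LocalModelFit(
        t_index=t,
        intercept=math.nan,
        beta=np.full(nz, math.nan),
        gamma=np.full(nx, math.nan),
        residual_sd=math.nan,
        n_fit=n,
        se=np.full(1 + nz + nx, math.nan),
        degenerate=True,
    )


def impute_cell(
    fit: LocalModelFit,
    window: np.ndarray,
    covariates: np.ndarray,
    rng: np.random.Generator,
) -> float:
    """One stochastic imputation draw for a single cell.

    ``window`` holds the de-meaned (lag2, lag1, lead1, lead2) values with
    unavailable entries already replaced by 0 (the de-meaned column mean).
    """
    if fit.degenerate:
        raise ValueError(f"cannot impute from degenerate fit at t={fit.t_index}")
    mu = float(fit.linear_predictor(window[None, :], covariates[None, :])[0])
    return mu + float(rng.normal(0.0, fit.residual_sd))


class ImputationProblem:
    """Wide-matrix view of an aligned cohort plus frozen de-meaning constants.

    ``values`` is (n_patients, n_intervals) with NaN at unobserved cells;
    ``observed`` marks the originally observed cells and ``in_window`` the
    cells between each patient's first and last observed interval — only
    those are ever imputed (no extrapolation beyond last contact).
    """

    def __init__(
        self,
        aligned: pd.DataFrame,
        covariates: pd.DataFrame,
    ) -> None:
        aligned = aligned.assign(patient_id=aligned["patient_id"].astype(str))
        pivot = aligned.pivot(
            index="patient_id", columns="t_index", values="value"
        ).sort_index()
        self.patient_ids = [str(p) for p in pivot.index]
        n, T = pivot.shape
        full = np.full((n, T), np.nan)
        cols = sorted(pivot.columns)
        for j, t in enumerate(cols):
            full[:, int(t)] = pivot[t].to_numpy(float)
        self.values = full
        self.observed = np.isfinite(full)
        if not self.observed.any(axis=1).all():
            bad = [p for p, row in zip(self.patient_ids, self.observed) if not row.any()]
            raise ValueError(f"patients with no observed cells: {bad[:5]}")
        first = self.observed.argmax(axis=1)
        last = T - 1 - self.observed[:, ::-1].argmax(axis=1)
        idx = np.arange(T)
        self.in_window = (idx >= first[:, None]) & (idx <= last[:, None])
        # frozen column means over originally observed values only
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(np.where(self.observed, full, np.nan), axis=0)
        overall = np.nanmean(full[self.observed]) if self.observed.any() else 0.0
        self.column_means = np.where(np.isfinite(col_mean), col_mean, overall)
        self.x, self.covariate_names = build_covariate_design(covariates, self.patient_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def initial_state(self) -> np.ndarray:
        """Mean-initialized state: in-window missing cells get the column mean."""
        state = self.values.copy()
        fill = ~self.observed & self.in_window
        state[fill] = np.broadcast_to(self.column_means, state.shape)[fill]
        return state

    def window_matrix(self, state: np.ndarray, t: int) -> np.ndarray:
        """De-meaned (lag2, lag1, lead1, lead2) columns at interval t.

        Entries outside the grid, outside a patient's window, or currently
        NaN are set to 0 — the de-meaned column mean.
        """
        n, T = state.shape
        z = np.zeros((n, len(WINDOW_OFFSETS)))
        for k, off in enumerate(WINDOW_OFFSETS):
            tt = t + off
            if 0 <= tt < T:
                col = state[:, tt] - self.column_means[tt]
                z[:, k] = np.where(np.isfinite(col), col, 0.0)
        return z


@dataclass
class ImputedDatasets:
    """The m completed grids plus diagnostics from the burn-in phase."""

    problem: ImputationProblem
    datasets: list[np.ndarray]
    burnin_used: int
    traces: pd.DataFrame  # iteration, t_index, coefficient, estimate, se
    master_seed: int

    @property
    def m(self) -> int:
        return len(self.datasets)

    def to_frame(self) -> pd.DataFrame:
        """Long format: imputation_id, patient_id, t_index, value, was_imputed."""
        rows = []
        prob = self.problem
        for j, ds in enumerate(self.datasets):
            for i, pid in enumerate(prob.patient_ids):
                for t in range(ds.shape[1]):
                    if not prob.in_window[i, t]:
                        continue
                    rows.append(
                        {
                            "imputation_id": j,
                            "patient_id": pid,
                            "t_index": t,
                            "value": ds[i, t],
                            "was_imputed": not prob.observed[i, t],
                        }
                    )
        return pd.DataFrame(
            rows, columns=["imputation_id", "patient_id", "t_index", "value", "was_imputed"]
        )


def _pmm_draw(
    fit: LocalModelFit,
    pred_missing: np.ndarray,
    pred_obs: np.ndarray,
    y_obs: np.ndarray,
    rng: np.random.Generator,
    k: int = 5,
) -> np.ndarray:
    """Predictive mean matching: draw each value from the k nearest donors."""
    out = np.empty(pred_missing.size)
    for i, p in enumerate(pred_missing):
        order = np.argsort(np.abs(pred_obs - p), kind="stable")[: min(k, y_obs.size)]
        out[i] = y_obs[int(rng.choice(order))]
    return out


def sweep(
    problem: ImputationProblem,
    state: np.ndarray,
    rng: np.random.Generator,
    pmm: bool = False,
    pmm_k: int = 5,
    record: list | None = None,
    iteration: int = -1,
) -> np.ndarray:
    """One forward pass over intervals: refit, then redraw missing cells.

    Operates on a copy of ``state``; observed cells are never modified.
    Degenerate intervals borrow the nearest previously fit-able model.
    """
    state = state.copy()
    n, T = state.shape
    last_good: LocalModelFit | None = None
    pending: list[int] = []  # intervals waiting for a first usable fit
    for t in range(T):
        obs_rows = problem.observed[:, t]
        z = problem.window_matrix(state, t)
        fit = fit_local_model(
            state[obs_rows, t], z[obs_rows], problem.x[obs_rows], t_index=t
        )
        if fit.degenerate:
            logger.debug("degenerate fit at t=%d (n=%d); borrowing neighbour", t, fit.n_fit)
            if last_good is None:
                pending.append(t)
                continue
            fit = last_good
        else:
            last_good = fit
            if record is not None:
                names = fit.coef_names(problem.covariate_names)
                for name, est, se in zip(names, fit.coef, fit.se):
                    record.append(
                        {
                            "iteration": iteration,
                            "t_index": t,
                            "coefficient": name,
                            "estimate": float(est),
                            "se": float(se),
                        }
                    )
        _redraw(problem, state, t, fit, rng, pmm, pmm_k)
        for t_back in pending:  # early intervals skipped before any fit existed
            zb = problem.window_matrix(state, t_back)
            _redraw(problem, state, t_back, fit, rng, pmm, pmm_k, z=zb)
        pending.clear()
    return state


def _redraw(
    problem: ImputationProblem,
    state: np.ndarray,
    t: int,
    fit: LocalModelFit,
    rng: np.random.Generator,
    pmm: bool,
    pmm_k: int,
    z: np.ndarray | None = None,
) -> None:
    target = ~problem.observed[:, t] & problem.in_window[:, t]
    if not target.any():
        return
    if z is None:
        z = problem.window_matrix(state, t)
    pred = fit.linear_predictor(z[target], problem.x[target])
    if pmm:
        obs_rows = problem.observed[:, t]
        if obs_rows.any():
            pred_obs = fit.linear_predictor(z[obs_rows], problem.x[obs_rows])
            state[target, t] = _pmm_draw(
                fit, pred, pred_obs, state[obs_rows, t], rng, pmm_k
            )
            return
    noise = rng.normal(0.0, fit.residual_sd, size=int(target.sum()))
    state[target, t] = pred + noise


def run_multiple_imputation(
    aligned: pd.DataFrame,
    covariates: pd.DataFrame,
    burnin: int = DEFAULT_BURNIN,
    m: int = DEFAULT_M,
    seed: int = 0,
    pmm: bool = False,
    independent_chains: bool = False,
) -> ImputedDatasets:
    """Burn in, then branch into m completed datasets.

    By default the m datasets share one burned-in chain and differ only in
    the final sweep's random stream; ``independent_chains=True`` runs m full
    chains instead.
    """
    problem = ImputationProblem(aligned, covariates)
    ss = np.random.SeedSequence(seed)
    trace_rows: list[dict] = []

    def _one_chain(chain_ss: np.random.SeedSequence, record: bool) -> np.ndarray:
        state = problem.initial_state()
        rng = np.random.default_rng(chain_ss)
        for it in range(burnin):
            state = sweep(
                problem,
                state,
                rng,
                pmm=pmm,
                record=trace_rows if record else None,
                iteration=it,
            )
        return state

    if independent_chains:
        children = ss.spawn(m)
        datasets = []
        for j, child in enumerate(children):
            burn_ss, final_ss = child.spawn(2)
            state = _one_chain(burn_ss, record=(j == 0))
            datasets.append(
                sweep(problem, state, np.random.default_rng(final_ss), pmm=pmm)
            )
    else:
        burn_ss, *final_sss = ss.spawn(m + 1)
        state = _one_chain(burn_ss, record=True)
        datasets = [
            sweep(problem, state, np.random.default_rng(fss), pmm=pmm)
            for fss in final_sss
        ]

    traces = pd.DataFrame(
        trace_rows, columns=["iteration", "t_index", "coefficient", "estimate", "se"]
    )
    return ImputedDatasets(problem, datasets, burnin, traces, seed)


CORE_COEFFICIENTS = ("intercept", *WINDOW_NAMES)
DEFAULT_CONVERGENCE_TOL = 0.15  # on the mean-|Δ| of core coefficients


def _trace_changes(traces: pd.DataFrame, core_only: bool) -> pd.DataFrame:
    wide = traces.pivot_table(
        index="iteration", columns=["t_index", "coefficient"], values="estimate"
    )
    if core_only:
        keep = [c for c in wide.columns if c[1] in CORE_COEFFICIENTS]
        wide = wide[keep]
    return wide.diff().abs()


def trace_max_changes(traces: pd.DataFrame, core_only: bool = True) -> pd.Series:
    """Max |Δ estimate| between successive burn-in iterations (index: iteration).

    By default restricted to the intercept and window coefficients, whose
    stabilization is the convergence criterion; covariate coefficients for
    rare categories are intrinsically noisier.
    """
    if traces.empty:
        return pd.Series(dtype=float)
    return _trace_changes(traces, core_only).max(axis=1).dropna()


def trace_mean_changes(traces: pd.DataFrame, core_only: bool = True) -> pd.Series:
    """Mean |Δ estimate| between successive burn-in iterations."""
    if traces.empty:
        return pd.Series(dtype=float)
    return _trace_changes(traces, core_only).mean(axis=1).dropna()


@dataclass
class RecoveryReport:
    n_masked: int
    rmse_pooled: float
    rmse_column_mean: float
    coverage: float  # fraction of truths inside the 2.5-97.5% imputation range


def mask_and_recover(
    complete_grid: pd.DataFrame,
    covariates: pd.DataFrame,
    mask_fraction: float,
    seed: int,
    burnin: int = DEFAULT_BURNIN,
    m: int = DEFAULT_M,
    pmm: bool = False,
) -> RecoveryReport:
    """Mask cells of a complete grid at random, impute, and score recovery.

    The first and last interval of each patient are kept observed so the
    follow-up window is preserved.  Pooled imputations (mean over the m
    draws) are scored against truth; column-mean imputation on the same
    mask serves as the baseline.
    """
    if not (0 < mask_fraction < 1):
        if mask_fraction == 0:
            return RecoveryReport(0, math.nan, math.nan, math.nan)
        raise ValueError("mask_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    grid = complete_grid.copy()
    grid["patient_id"] = grid["patient_id"].astype(str)
    pivot = grid.pivot(index="patient_id", columns="t_index", values="value")
    truth = pivot.to_numpy(float)
    if np.isnan(truth).any():
        raise ValueError("complete_grid must have no missing cells")
    n, T = truth.shape
    maskable = np.ones((n, T), bool)
    maskable[:, 0] = False
    maskable[:, T - 1] = False
    cand = np.argwhere(maskable)
    n_mask = int(round(mask_fraction * cand.shape[0]))
    if n_mask == 0:
        return RecoveryReport(0, math.nan, math.nan, math.nan)
    chosen = cand[rng.choice(cand.shape[0], size=n_mask, replace=False)]
    masked = np.zeros((n, T), bool)
    masked[chosen[:, 0], chosen[:, 1]] = True

    rows = []
    for i, pid in enumerate(pivot.index):
        for t in range(T):
            rows.append(
                {
                    "patient_id": pid,
                    "t_index": t,
                    "value": math.nan if masked[i, t] else truth[i, t],
                }
            )
    aligned = pd.DataFrame(rows)
    result = run_multiple_imputation(
        aligned, covariates, burnin=burnin, m=m, seed=seed, pmm=pmm
    )
    order = {p: i for i, p in enumerate(result.problem.patient_ids)}
    perm = np.array([order[p] for p in pivot.index])
    stack = np.stack([ds[perm] for ds in result.datasets])  # (m, n, T)

    pooled = stack.mean(axis=0)
    err = pooled[masked] - truth[masked]
    rmse = float(np.sqrt(np.mean(err**2)))

    col_means = np.nanmean(np.where(masked, np.nan, truth), axis=0)
    cm_err = np.broadcast_to(col_means, truth.shape)[masked] - truth[masked]
    rmse_cm = float(np.sqrt(np.mean(cm_err**2)))

    lo = np.quantile(stack, 0.025, axis=0)
    hi = np.quantile(stack, 0.975, axis=0)
    inside = (truth[masked] >= lo[masked]) & (truth[masked] <= hi[masked])
    return RecoveryReport(n_mask, rmse, rmse_cm, float(inside.mean()))
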