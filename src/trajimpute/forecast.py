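"""Feature construction and learners for 1- and 2-interval-ahead forecasts.

Two feature specifications are supported.  FULL uses the current value and
the two preceding intervals; SKIPPED withholds the previous interval's
value — mimicking an intentionally extended monitoring gap — and uses the
current value plus the change since two intervals ago instead.  Both carry
current and previous-interval adherence, age at diagnosis, and time since
diagnosis.  Learners: a gradient-boosted tree ensemble and a small
recurrent network; both expose seeded, reproducible training and a
bootstrap-ensemble route to within-model prediction variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingRegressor

from .rnn import RNNConfig, RecurrentRegressor

logger = logging.getLogger(__name__)

SPEC_FULL = "FULL"
SPEC_SKIPPED = "SKIPPED"
LEARNER_GB = "xgboost"  # gradient-boosted trees (paper's role)
LEARNER_RNN = "rnn"

FULL_COLUMNS = ["y_t", "y_lag1", "y_lag2", "adh_t", "adh_lag1", "age_at_dx", "time_since_dx"]
SKIPPED_COLUMNS = ["y_t", "delta_6mo", "adh_t", "adh_lag1", "age_at_dx", "time_since_dx"]
# chronological order of the sequence fed to the recurrent learner
SEQUENCE_COLUMNS = {SPEC_FULL: ["y_lag2", "y_lag1", "y_t"], SPEC_SKIPPED: ["delta_6mo", "y_t"]}


def feature_columns(spec: str) -> list[str]:
    if spec == SPEC_FULL:
        return list(FULL_COLUMNS)
    if spec == SPEC_SKIPPED:
        return list(SKIPPED_COLUMNS)
    raise ValueError(f"unknown spec {spec!r}")


def build_features(
    grid: pd.DataFrame,
    adherence: pd.DataFrame,
    covariates: pd.DataFrame,
    spec: str,
    horizon: int,
    grid_days: int = 90,
) -> pd.DataFrame:
    """Feature/target rows from one completed grid.

    ``grid`` is long format (patient_id, t_index, value) and must be
    complete within each patient's span; rows are emitted for origins t >= 2
    with t+horizon inside the patient's span.  Adherence indices absent from
    the adherence table count as 0 (no recorded supply).
    """
    if horizon not in (1, 2):
        raise ValueError("horizon must be 1 or 2")
    cols = feature_columns(spec)
    grid = grid.assign(patient_id=grid["patient_id"].astype(str))
    if grid["value"].isna().any():
        raise ValueError("grid has missing values; run imputation first")
    adh = {
        (str(r.patient_id), int(r.t_index)): float(r.adherence)
        for r in adherence.itertuples()
    }
    cov = covariates.set_index(covariates["patient_id"].astype(str))

    rows = []
    n_dropped = 0
    for pid, grp in grid.groupby("patient_id", sort=True):
        series = dict(zip(grp["t_index"].astype(int), grp["value"].astype(float)))
        ts = sorted(series)
        age = float(cov.loc[pid, "age_at_dx"])
        for t in ts:
            if t < 2 or (t + horizon) not in series:
                n_dropped += 1
                continue
            if (t - 1) not in series or (t - 2) not in series:
                n_dropped += 1
                continue
            feats = {
                "y_t": series[t],
                "y_lag1": series[t - 1],
                "y_lag2": series[t - 2],
                "delta_6mo": series[t] - series[t - 2],
                "adh_t": adh.get((pid, t), 0.0),
                "adh_lag1": adh.get((pid, t - 1), 0.0),
                "age_at_dx": age,
                "time_since_dx": float(grid_days * t),
            }
            rows.append(
                {
                    "patient_id": pid,
                    "t_index": t,
                    **{c: feats[c] for c in cols},
                    "target": series[t + horizon],
                }
            )
    if n_dropped:
        logger.debug("build_features(%s, h=%d): dropped %d boundary rows", spec, horizon, n_dropped)
    return pd.DataFrame(rows, columns=["patient_id", "t_index", *cols, "target"])


def split_patients(patient_ids: list[str], fraction: float = 0.8, seed: int = 0) -> dict[str, str]:
    """Patient-level train/test split, deterministic under seed."""
    ids = sorted(set(str(p) for p in patient_ids))
    if len(ids) < 5:
        raise ValueError("need at least 5 patients to split")
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    assignment = {}
    for rank, j in enumerate(perm):
        assignment[ids[j]] = "TRAIN" if rank < n_train else "TEST"
    return assignment


@dataclass
class LearnerConfig:
    # gradient boosting
    gb_n_trees: int = 500
    gb_max_depth: int = 4
    gb_learning_rate: float = 0.05
    gb_early_stopping: bool = True
    # recurrent net
    rnn: RNNConfig = field(default_factory=RNNConfig)
    # bootstrap ensemble for within-imputation prediction variance
    bootstrap_members: int = 20


class _GBModel:
    def __init__(self, spec: str, config: LearnerConfig, seed: int) -> None:
        self.spec = spec
        self._est = HistGradientBoostingRegressor(
            max_iter=config.gb_n_trees,
            max_depth=config.gb_max_depth,
            learning_rate=config.gb_learning_rate,
            early_stopping=config.gb_early_stopping,
            random_state=seed,
        )

    def fit(self, rows: pd.DataFrame) -> "_GBModel":
        cols = feature_columns(self.spec)
        self._est.fit(rows[cols].to_numpy(float), rows["target"].to_numpy(float))
        return self

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        return self._est.predict(rows[feature_columns(self.spec)].to_numpy(float))


class _RNNModel:
    def __init__(self, spec: str, config: LearnerConfig, seed: int) -> None:
        self.spec = spec
        self._net = RecurrentRegressor(config.rnn, seed=seed)

    def _split_features(self, rows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        seq_cols = SEQUENCE_COLUMNS[self.spec]
        static_cols = [c for c in feature_columns(self.spec) if c not in seq_cols]
        return rows[seq_cols].to_numpy(float), rows[static_cols].to_numpy(float)

    def fit(self, rows: pd.DataFrame) -> "_RNNModel":
        seq, static = self._split_features(rows)
        self._net.fit(seq, static, rows["target"].to_numpy(float))
        return self

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        return self._net.predict(*self._split_features(rows))


def train_learner(
    train_rows: pd.DataFrame,
    learner: str,
    spec: str,
    config: LearnerConfig | None = None,
    seed: int = 0,
):
    """Fit one learner on a feature table; returns a model with .predict()."""
    if train_rows.empty:
        raise ValueError("empty training data")
    cols = feature_columns(spec) + ["target"]
    if train_rows[cols].isna().any().any():
        raise ValueError("NaN in features or target")
    config = config or LearnerConfig()
    if learner == LEARNER_GB:
        return _GBModel(spec, config, seed).fit(train_rows)
    if learner == LEARNER_RNN:
        return _RNNModel(spec, config, seed).fit(train_rows)
    raise ValueError(f"unknown learner {learner!r}")


def bootstrap_ensemble(
    train_rows: pd.DataFrame,
    learner: str,
    spec: str,
    config: LearnerConfig,
    seed: int,
) -> list:
    """B refits on bootstrap resamples of the training rows."""
    rng = np.random.default_rng(seed)
    members = []
    n = len(train_rows)
    for b in range(config.bootstrap_members):
        idx = rng.integers(0, n, size=n)
        sub = train_rows.iloc[idx].reset_index(drop=True)
        members.append(train_learner(sub, learner, spec, config, seed=int(rng.integers(2**31))))
    return members


def predict_with_uncertainty(
    model,
    rows: pd.DataFrame,
    ensemble: list | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Point predictions plus a per-row within-model variance.

    Variance is the spread across bootstrap-ensemble members; with no
    ensemble (or a single member) it is 0.
    """
    point = np.asarray(model.predict(rows), float)
    if not ensemble or len(ensemble) < 2:
        return point, np.zeros_like(point)
    preds = np.stack([np.asarray(mem.predict(rows), float) for mem in ensemble])
    return point, preds.var(axis=0, ddof=1)


def run_forecast(
    imputed: pd.DataFrame,
    adherence: pd.DataFrame,
    covariates: pd.DataFrame,
    learners: list[str],
    specs: list[str],
    horizons: list[int],
    train_fraction: float = 0.8,
    seed: int = 0,
    config: LearnerConfig | None = None,
    grid_days: int = 90,
) -> pd.DataFrame:
    """Train/test every (imputation, learner, spec, horizon) combination.

    The patient-level split is drawn once and reused everywhere so that
    pooling across imputations is coherent.  Returns the long prediction
    table with targets and within-model variances.
    """
    config = config or LearnerConfig()
    pids = sorted(imputed["patient_id"].astype(str).unique())
    assignment = split_patients(pids, train_fraction, seed)
    out = []
    for imp_id, grid in imputed.groupby("imputation_id"):
        grid = grid[["patient_id", "t_index", "value"]]
        for spec in specs:
            for horizon in horizons:
                feats = build_features(grid, adherence, covariates, spec, horizon, grid_days)
                is_train = feats["patient_id"].map(assignment) == "TRAIN"
                train_rows = feats[is_train].reset_index(drop=True)
                test_rows = feats[~is_train].reset_index(drop=True)
                if train_rows.empty or test_rows.empty:
                    logger.warning(
                        "empty split for imputation=%s spec=%s horizon=%d", imp_id, spec, horizon
                    )
                    continue
                for learner in learners:
                    fit_seed = int(
                        np.random.SeedSequence(
                            [seed, int(imp_id), horizons.index(horizon), specs.index(spec), learners.index(learner)]
                        ).generate_state(1)[0]
                    )
                    model = train_learner(train_rows, learner, spec, config, seed=fit_seed)
                    ensemble = (
                        bootstrap_ensemble(train_rows, learner, spec, config, seed=fit_seed)
                        if config.bootstrap_members >= 2
                        else None
                    )
                    pred, within = predict_with_uncertainty(model, test_rows, ensemble)
                    out.append(
                        pd.DataFrame(
                            {
                                "imputation_id": imp_id,
                                "learner": learner,
                                "spec": spec,
                                "horizon": horizon,
                                "patient_id": test_rows["patient_id"],
                                "t_index": test_rows["t_index"],
                                "prediction": pred,
                                "within_variance": within,
                                "target": test_rows["target"],
                            }
                        )
                    )
    if not out:
        return pd.DataFrame(
            columns=[
                "imputation_id", "learner", "spec", "horizon", "patient_id",
                "t_index", "prediction", "within_variance", "target",
            ]
        )
    return pd.concat(out, ignore_index=True)
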