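"""Synthetic cohort generator for end-to-end testing of the pipeline.

Real monitoring data of this kind are access-restricted, so the package
ships a generator that reproduces the *statistical structure* downstream
stages assume: a sharp early decline of standardized values to a patient
plateau, AR(1) wiggle so that neighbouring intervals carry signal,
irregular visit timing around a regular schedule, value- and
adherence-dependent visit skipping, and pharmacy dispensation histories
with imperfect refill behaviour.

Default parameters are calibrated so a large cohort has marginal SD near
2.8 on the standardized scale with values spanning roughly (-8.3, 1.1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .adherence import DispensationRecord
from .preprocess import RawMeasurementSeries


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 500
    followup_days: int = 3600
    grid_days: int = 90
    # latent trajectory: max(plateau, baseline - rate*day) + AR(1)
    baseline_mean: float = 0.0
    baseline_sd: float = 0.6
    plateau_mean: float = -5.0
    plateau_sd: float = 0.9
    # two-component plateau mixture: deep vs partial responders, component
    # means at plateau_mean -/+ plateau_mix_separation/2
    plateau_mix_prob: float = 0.5
    plateau_mix_separation: float = 5.8
    decline_rate_mean: float = 0.022
    decline_rate_sd: float = 0.009
    ar_rho: float = 0.3
    ar_sd: float = 0.7
    noise_sd: float = 0.35
    value_min: float = -8.29
    value_max: float = 1.08
    # visit process
    visit_jitter_days: int = 21
    skip_prob_base: float = -1.4
    skip_prob_value_coef: float = -0.18
    skip_prob_adherence_coef: float = 0.8
    # adherence / dispensations
    adherence_alpha: float = 5.0
    adherence_beta: float = 1.6
    fill_supply_days: int = 30
    refill_delay_days: int = 0
    # assay formats: label -> nominal median baseline raw value
    format_medians: dict[str, float] = field(
        default_factory=lambda: {"IS_PCT": 45.0, "RATIO": 0.45}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.grid_days <= 0 or self.followup_days <= 0:
            raise ValueError("grid_days and followup_days must be positive")
        for name in ("baseline_sd", "plateau_sd", "decline_rate_sd", "ar_sd", "noise_sd"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not (0 <= self.plateau_mix_prob <= 1):
            raise ValueError("plateau_mix_prob must be in [0, 1]")
        if self.plateau_mix_separation < 0:
            raise ValueError("plateau_mix_separation must be >= 0")
        if not (0 <= self.ar_rho < 1):
            raise ValueError("ar_rho must be in [0, 1)")
        if self.value_min >= self.value_max:
            raise ValueError("value_min must be < value_max")
        if self.visit_jitter_days < 0 or self.visit_jitter_days >= self.grid_days // 2:
            raise ValueError("visit_jitter_days must be in [0, grid_days/2)")
        if self.adherence_alpha <= 0 or self.adherence_beta <= 0:
            raise ValueError("adherence beta-shape parameters must be > 0")
        if self.fill_supply_days <= 0:
            raise ValueError("fill_supply_days must be > 0")
        for name in ("skip_prob_base", "skip_prob_value_coef", "skip_prob_adherence_coef"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    true_grid: pd.DataFrame  # patient_id, t_index, value — complete
    measurements: list[RawMeasurementSeries]
    dispensations: list[DispensationRecord]
    covariates: pd.DataFrame
    adherence_propensity: dict[str, float]
    format_assignment: dict[str, str]
    seed_used: int

    @property
    def format_medians(self) -> dict[str, float]:
        return dict(self.config.format_medians)


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # one stream per patient keyed on (seed, index): reproducible under reordering
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def latent_trajectory(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, float]]:
    """Latent standardized values at grid indices 0..T for one patient."""
    n_t = config.followup_days // config.grid_days + 1
    baseline = _truncnorm(
        rng, config.baseline_mean, config.baseline_sd, config.value_min, config.value_max
    )
    deep = rng.random() < config.plateau_mix_prob
    half = config.plateau_mix_separation / 2.0
    plat_mean = config.plateau_mean + (-half if deep else half)
    plateau = _truncnorm(
        rng, plat_mean, config.plateau_sd, config.value_min, min(baseline, config.value_max)
    )
    rate = _truncnorm(rng, config.decline_rate_mean, config.decline_rate_sd, 1e-6, 1.0)
    days = np.arange(n_t) * config.grid_days
    trend = np.maximum(plateau, baseline - rate * days)
    # stationary AR(1) around the trend
    e = np.zeros(n_t)
    if config.ar_sd > 0:
        e[0] = rng.normal(0, config.ar_sd)
        innov_sd = config.ar_sd * math.sqrt(1 - config.ar_rho**2)
        for t in range(1, n_t):
            e[t] = config.ar_rho * e[t - 1] + rng.normal(0, innov_sd)
    latent = np.clip(trend + e, config.value_min, config.value_max)
    params = {"baseline": baseline, "plateau": plateau, "rate": rate}
    return latent, params


def simulate_dispensations(
    adherence_propensity: float,
    followup_days: int,
    fill_supply_days: int,
    rng: np.random.Generator,
    refill_delay_days: int = 0,
    patient_id: str = "",
) -> list[DispensationRecord]:
    """Dispensation history under a Bernoulli refill process.

    The first fill always happens at day 0.  Every subsequent refill is due
    when the prior supply runs out; it occurs with probability equal to the
    patient's adherence propensity (plus an optional fixed delay), otherwise
    that refill cycle is missed and the next opportunity comes one supply
    duration later.  Propensity 1 with zero delay yields gap-free supply.
    """
    if not (0 <= adherence_propensity <= 1):
        raise ValueError("adherence_propensity must be in [0, 1]")
    fills = [DispensationRecord(patient_id, 0, fill_supply_days)]
    due = fill_supply_days
    while due < followup_days:
        if rng.random() < adherence_propensity:
            fill_day = due + refill_delay_days
            if fill_day >= followup_days:
                break
            fills.append(DispensationRecord(patient_id, fill_day, fill_supply_days))
            due = fill_day + fill_supply_days
        else:
            due += fill_supply_days
    return fills


def simulate_patient(
    config: SimulationConfig, index: int
) -> tuple[np.ndarray, RawMeasurementSeries, list[DispensationRecord], dict, float, str]:
    rng = _patient_rng(config.seed, index)
    pid = f"P{index:04d}"
    latent, _ = latent_trajectory(config, rng)
    n_t = latent.size

    propensity = float(rng.beta(config.adherence_alpha, config.adherence_beta))
    dispensations = simulate_dispensations(
        propensity,
        config.followup_days,
        config.fill_supply_days,
        rng,
        config.refill_delay_days,
        pid,
    )

    fmt = str(rng.choice(sorted(config.format_medians)))
    median = config.format_medians[fmt]

    # visit process: one scheduled visit per grid index, jittered, skippable
    visit_ts: list[int] = []
    for t in range(n_t):
        logit = (
            config.skip_prob_base
            + config.skip_prob_value_coef * latent[t]
            + config.skip_prob_adherence_coef * (1 - propensity)
        )
        skip = rng.random() < _logistic(logit)
        if t == 0 or not skip:
            visit_ts.append(t)
    if len(visit_ts) < 2:  # cohort rule: >= 2 measurements per patient
        visit_ts.append(1 if n_t > 1 else 0)
        visit_ts = sorted(set(visit_ts))

    records: list[tuple[int, float, str]] = []
    for t in visit_ts:
        jitter = (
            int(rng.integers(-config.visit_jitter_days, config.visit_jitter_days + 1))
            if config.visit_jitter_days > 0
            else 0
        )
        day = max(0, t * config.grid_days + jitter)
        std_val = latent[t] + (rng.normal(0, config.noise_sd) if config.noise_sd > 0 else 0.0)
        raw = median * math.exp(std_val)
        records.append((day, raw, fmt))
    # jitter can reorder or collide; keep one record per day, sorted
    dedup: dict[int, tuple[int, float, str]] = {}
    for rec in records:
        dedup.setdefault(rec[0], rec)
    records = sorted(dedup.values())
    if len(records) < 2:
        day2 = records[0][0] + config.grid_days
        records.append((day2, median * math.exp(float(latent[min(1, n_t - 1)])), fmt))
    series = RawMeasurementSeries(pid, records)

    age = _truncnorm(rng, 54.6, 16.5, 18.5, 95.0)
    bmi = _truncnorm(rng, 29.4, 6.6, 15.0, 60.0)
    sex = "M" if rng.random() < 0.612 else "F"
    tx = str(rng.choice(["imatinib", "dasatinib", "nilotinib"], p=[0.802, 0.161, 0.037]))
    covars = {
        "patient_id": pid,
        "age_at_dx": round(age, 1),
        "bmi": round(bmi, 1),
        "sex": sex,
        "first_line_treatment": tx,
    }
    return latent, series, dispensations, covars, propensity, fmt


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort. Identical configs give identical cohorts."""
    config.validate()
    true_rows = []
    measurements: list[RawMeasurementSeries] = []
    dispensations: list[DispensationRecord] = []
    covariate_rows = []
    propensities: dict[str, float] = {}
    formats: dict[str, str] = {}
    for i in range(config.n_patients):
        latent, series, disp, covars, prop, fmt = simulate_patient(config, i)
        pid = series.patient_id
        for t, v in enumerate(latent):
            true_rows.append({"patient_id": pid, "t_index": t, "value": float(v)})
        measurements.append(series)
        dispensations.extend(disp)
        covariate_rows.append(covars)
        propensities[pid] = prop
        formats[pid] = fmt
    return SyntheticCohort(
        config=config,
        true_grid=pd.DataFrame(true_rows),
        measurements=measurements,
        dispensations=dispensations,
        covariates=pd.DataFrame(covariate_rows),
        adherence_propensity=propensities,
        format_assignment=formats,
        seed_used=config.seed,
    )


def cohort_tables(cohort: SyntheticCohort) -> dict[str, pd.DataFrame]:
    """The flat CSV tables downstream stages consume, plus the truth grid."""
    meas_rows = [
        {"patient_id": s.patient_id, "day": d, "raw_value": raw, "assay_format": fmt}
        for s in cohort.measurements
        for d, raw, fmt in s.records
    ]
    disp_rows = [
        {"patient_id": d.patient_id, "fill_day": d.fill_day, "days_supplied": d.days_supplied}
        for d in cohort.dispensations
    ]
    treat_rows = [
        {"patient_id": s.patient_id, "treatment_start_day": 0} for s in cohort.measurements
    ]
    return {
        "measurements": pd.DataFrame(meas_rows),
        "treatment": pd.DataFrame(treat_rows),
        "dispensations": pd.DataFrame(disp_rows),
        "covariates": cohort.covariates,
        "true_grid": cohort.true_grid,
    }
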