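"""Standardization of raw biomarker values and alignment to a regular grid.

Raw measurements arrive on irregular days and in heterogeneous assay
formats.  This module (1) picks a per-patient baseline day, (2) maps raw
values to a common scale via a log-ratio against the format-specific
median baseline, and (3) snaps the standardized series onto a regular
``grid_days`` index, matching each grid point to the nearest observation
within ``match_window_days`` and marking unmatched points missing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_GRID_DAYS = 90
DEFAULT_MATCH_WINDOW_DAYS = 45


@dataclass(frozen=True)
class RawMeasurementSeries:
    """Per-patient irregular raw biomarker observations.

    ``records`` is a list of ``(day, raw_value, assay_format)`` tuples with
    strictly increasing non-negative-or-negative days (pre-treatment days may
    be negative relative to a later anchor, but must be increasing) and
    strictly positive raw values.
    """

    patient_id: str
    records: list[tuple[int, float, str]]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError(
                f"patient {self.patient_id}: at least 2 measurements required, "
                f"got {len(self.records)}"
            )
        days = [r[0] for r in self.records]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"patient {self.patient_id}: days must be strictly increasing")
        for day, raw, fmt in self.records:
            if not math.isfinite(raw) or raw <= 0:
                raise ValueError(
                    f"patient {self.patient_id}: raw value must be finite and > 0 "
                    f"(day {day}: {raw})"
                )

    @property
    def days(self) -> list[int]:
        return [r[0] for r in self.records]


@dataclass(frozen=True)
class StandardizedSeries:
    """Log-ratio standardized series for one patient."""

    patient_id: str
    records: list[tuple[int, float]]  # (day, std_value)
    baseline_day: int


@dataclass
class AlignedGrid:
    """Standardized values on a regular grid index for one patient.

    ``values[t]`` is NaN where no observation fell inside the matching
    window; ``matched_day[t]`` is the source day of the match or None.
    """

    patient_id: str
    values: list[float]  # NaN == missing
    matched_days: list[int | None]
    grid_days: int = DEFAULT_GRID_DAYS

    def __post_init__(self) -> None:
        if len(self.values) != len(self.matched_days):
            raise ValueError("values and matched_days must have equal length")

    @property
    def n_intervals(self) -> int:
        return len(self.values)

    def is_missing(self, t: int) -> bool:
        return math.isnan(self.values[t])


def select_baseline(series: RawMeasurementSeries, treatment_start_day: int) -> int:
    """Pick the baseline day for a patient.

    Prefers the pre-treatment record closest to treatment start; when no
    pre-treatment record exists, falls back to the earliest post-treatment
    record.  Ties on distance go to the earlier day.
    """
    pre = [d for d in series.days if d < treatment_start_day]
    if pre:
        return min(pre, key=lambda d: (abs(d - treatment_start_day), d))
    post = [d for d in series.days if d >= treatment_start_day]
    return min(post)


def compute_format_medians(
    cohort: list[RawMeasurementSeries],
    baseline_days: dict[str, int],
    min_patients_warn: int = 3,
) -> dict[str, float]:
    """Median baseline raw value per assay format across the cohort.

    The baseline record of each patient (located by ``baseline_days``)
    contributes to the median of its own assay format.  Formats backed by
    fewer than ``min_patients_warn`` patients are still tabulated but a
    warning is logged.
    """
    per_format: dict[str, list[float]] = {}
    for series in cohort:
        b_day = baseline_days[series.patient_id]
        rec = next(r for r in series.records if r[0] == b_day)
        per_format.setdefault(rec[2], []).append(rec[1])
    medians: dict[str, float] = {}
    for fmt, vals in per_format.items():
        if len(vals) < min_patients_warn:
            logger.warning(
                "assay format %r has only %d baseline value(s); median may be unstable",
                fmt,
                len(vals),
            )
        medians[fmt] = float(np.median(vals))
    return medians


def standardize(
    series: RawMeasurementSeries,
    medians: dict[str, float],
    baseline_day: int,
    log_base: str = "natural",
) -> StandardizedSeries:
    """Standardize raw values as log(raw / format_median_baseline).

    ``log_base`` is ``"natural"`` or ``"base10"``.  Days are re-anchored so
    that the baseline day becomes day 0.
    """
    if log_base not in ("natural", "base10"):
        raise ValueError(f"unknown log base {log_base!r}")
    logf = math.log if log_base == "natural" else math.log10
    out: list[tuple[int, float]] = []
    for day, raw, fmt in series.records:
        if fmt not in medians:
            raise KeyError(f"no median for assay format {fmt!r}")
        med = medians[fmt]
        if med <= 0:
            raise ValueError(f"median for format {fmt!r} must be > 0")
        out.append((day - baseline_day, logf(raw / med)))
    return StandardizedSeries(series.patient_id, out, baseline_day)


def destandardize(std_value: float, median: float, log_base: str = "natural") -> float:
    """Inverse of :func:`standardize` for a single value."""
    base = math.e if log_base == "natural" else 10.0
    return median * base**std_value


def align_to_grid(
    series: StandardizedSeries,
    grid_days: int = DEFAULT_GRID_DAYS,
    match_window_days: int = DEFAULT_MATCH_WINDOW_DAYS,
) -> AlignedGrid:
    """Assign standardized observations to grid points 0, g, 2g, ...

    Pairs are assigned greedily by ascending |day - g*t|; ties break to the
    earlier observation day, then to the earlier grid index.  Each
    observation serves at most one grid point and vice versa.  The grid
    extends to the last index whose date is at most ``final_day +
    match_window_days`` so that the final observation remains matchable.
    """
    days = np.array([d for d, _ in series.records])
    vals = np.array([v for _, v in series.records])
    post = days >= -match_window_days  # only obs matchable to t >= 0
    days, vals = days[post], vals[post]

    final_day = int(days.max()) if days.size else 0
    n_t = (final_day + match_window_days) // grid_days + 1

    values = [math.nan] * n_t
    matched: list[int | None] = [None] * n_t

    pairs = []
    for t in range(n_t):
        target = grid_days * t
        for j in range(days.size):
            dist = abs(int(days[j]) - target)
            if dist <= match_window_days:
                pairs.append((dist, int(days[j]), t, j))
    pairs.sort()

    used_obs: set[int] = set()
    used_t: set[int] = set()
    for dist, day, t, j in pairs:
        if j in used_obs or t in used_t:
            continue
        used_obs.add(j)
        used_t.add(t)
        values[t] = float(vals[j])
        matched[t] = day
    return AlignedGrid(series.patient_id, values, matched, grid_days)


def cohort_to_frame(grids: list[AlignedGrid]) -> pd.DataFrame:
    """Long-format frame (patient_id, t_index, value, matched_day)."""
    rows = []
    for g in grids:
        for t in range(g.n_intervals):
            rows.append(
                {
                    "patient_id": g.patient_id,
                    "t_index": t,
                    "value": g.values[t],
                    "matched_day": g.matched_days[t],
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "t_index", "value", "matched_day"])


def run_preprocess(
    measurements: pd.DataFrame,
    treatment: pd.DataFrame,
    grid_days: int = DEFAULT_GRID_DAYS,
    match_window_days: int = DEFAULT_MATCH_WINDOW_DAYS,
    log_base: str = "natural",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Full preprocessing stage on tabular inputs.

    ``measurements`` columns: patient_id, day, raw_value, assay_format.
    ``treatment`` columns: patient_id, treatment_start_day.
    Returns the aligned long-format frame and the format median table.
    """
    tx = dict(zip(treatment["patient_id"].astype(str), treatment["treatment_start_day"]))
    cohort: list[RawMeasurementSeries] = []
    for pid, grp in measurements.groupby("patient_id", sort=True):
        grp = grp.sort_values("day")
        recs = [
            (int(r.day), float(r.raw_value), str(r.assay_format))
            for r in grp.itertuples()
        ]
        cohort.append(RawMeasurementSeries(str(pid), recs))
    baseline_days = {
        s.patient_id: select_baseline(s, int(tx.get(s.patient_id, 0))) for s in cohort
    }
    medians = compute_format_medians(cohort, baseline_days)
    grids = []
    for s in cohort:
        std = standardize(s, medians, baseline_days[s.patient_id], log_base)
        grids.append(align_to_grid(std, grid_days, match_window_days))
    return cohort_to_frame(grids), medians
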