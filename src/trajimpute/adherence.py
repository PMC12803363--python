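"""Interval-level medication adherence from pharmacy dispensation records.

Implements the availability-with-carry-over convention: each fill's supply
starts when the previous supply runs out (or at the fill day, whichever is
later), oversupply rolls forward, and nothing is counted past the
observation end.  Adherence for interval ``t`` is the fraction of days in
``[g*t, g*(t+1))`` covered by supply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_GRID_DAYS


@dataclass(frozen=True)
class DispensationRecord:
    patient_id: str
    fill_day: int
    days_supplied: int

    def __post_init__(self) -> None:
        if self.days_supplied <= 0:
            raise ValueError(
                f"days_supplied must be positive, got {self.days_supplied}"
            )


def coverage_intervals(
    dispensations: list[DispensationRecord], observation_end: int
) -> list[tuple[int, int]]:
    """Half-open [start, end) day ranges covered by supply, with carry-over."""
    fills = sorted(dispensations, key=lambda d: d.fill_day)
    if any(f.fill_day != s.fill_day for f, s in zip(dispensations, fills)):
        raise ValueError("dispensations must be sorted by fill_day")
    out: list[tuple[int, int]] = []
    supply_end = 0
    for d in fills:
        start = max(d.fill_day, supply_end)
        end = start + d.days_supplied
        supply_end = end
        start = min(start, observation_end)
        end = min(end, observation_end)
        if end > start:
            out.append((start, end))
    return out


def compute_cma9(
    dispensations: list[DispensationRecord],
    observation_end: int,
    grid_days: int = DEFAULT_GRID_DAYS,
) -> np.ndarray:
    """Adherence per grid interval, each in [0, 1].

    Returns an array of length ``ceil(observation_end / grid_days)``;
    intervals before the first fill get 0.
    """
    if observation_end <= 0:
        return np.zeros(0)
    n_t = -(-observation_end // grid_days)  # ceil
    covered = np.zeros(n_t)
    for start, end in coverage_intervals(dispensations, observation_end):
        t0, t1 = start // grid_days, (end - 1) // grid_days
        for t in range(t0, t1 + 1):
            lo = max(start, t * grid_days)
            hi = min(end, (t + 1) * grid_days)
            covered[t] += max(0, hi - lo)
    return np.minimum(covered / grid_days, 1.0)


def adherence_frame(
    dispensations: pd.DataFrame,
    observation_ends: dict[str, int],
    grid_days: int = DEFAULT_GRID_DAYS,
) -> pd.DataFrame:
    """Long-format adherence table (patient_id, t_index, adherence).

    ``dispensations`` columns: patient_id, fill_day, days_supplied.  Patients
    present in ``observation_ends`` but absent from the dispensation table
    get all-zero adherence.
    """
    by_patient: dict[str, list[DispensationRecord]] = {
        pid: [] for pid in observation_ends
    }
    for r in dispensations.itertuples():
        pid = str(r.patient_id)
        if pid in by_patient:
            by_patient[pid].append(
                DispensationRecord(pid, int(r.fill_day), int(r.days_supplied))
            )
    rows = []
    for pid, end in observation_ends.items():
        fills = sorted(by_patient[pid], key=lambda d: d.fill_day)
        series = compute_cma9(fills, end, grid_days)
        for t, a in enumerate(series):
            rows.append({"patient_id": pid, "t_index": t, "adherence": float(a)})
    return pd.DataFrame(rows, columns=["patient_id", "t_index", "adherence"])
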