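"""Pipeline configuration: a flat YAML key-value file with strict loading."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .forecast import LEARNER_GB, LEARNER_RNN, SPEC_FULL, SPEC_SKIPPED


@dataclass
class PipelineConfig:
    workdir: str = "."
    grid_days: int = 90
    match_window_days: int = 45
    log_base: str = "natural"  # or "base10"
    burnin: int = 15
    m: int = 10
    pmm: bool = False
    train_fraction: float = 0.8
    learners: list[str] = field(default_factory=lambda: [LEARNER_RNN, LEARNER_GB])
    specs: list[str] = field(default_factory=lambda: [SPEC_FULL, SPEC_SKIPPED])
    horizons: list[int] = field(default_factory=lambda: [1, 2])
    seed: int = 0
    # simulator overrides (forwarded to SimulationConfig)
    n_patients: int = 200
    followup_days: int = 2700
    # learner sizing
    gb_n_trees: int = 500
    gb_max_depth: int = 4
    gb_learning_rate: float = 0.05
    rnn_hidden_size: int = 32
    rnn_max_epochs: int = 300
    bootstrap_members: int = 20

    def validate(self) -> None:
        if self.grid_days <= 0 or self.match_window_days <= 0:
            raise ValueError("grid_days and match_window_days must be positive")
        if self.match_window_days > self.grid_days:
            raise ValueError("match_window_days must not exceed grid_days")
        if self.log_base not in ("natural", "base10"):
            raise ValueError("log_base must be 'natural' or 'base10'")
        if self.burnin < 0 or self.m < 1:
            raise ValueError("burnin must be >= 0 and m >= 1")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        bad = set(self.learners) - {LEARNER_GB, LEARNER_RNN}
        if bad:
            raise ValueError(f"unknown learner(s): {sorted(bad)}")
        bad = set(self.specs) - {SPEC_FULL, SPEC_SKIPPED}
        if bad:
            raise ValueError(f"unknown spec(s): {sorted(bad)}")
        if set(self.horizons) - {1, 2}:
            raise ValueError("horizons must be a subset of {1, 2}")


def load_config(path: str | None, **overrides) -> PipelineConfig:
    """Load YAML config; unknown keys are rejected; overrides win."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise KeyError(f"unknown config key(s): {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg
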