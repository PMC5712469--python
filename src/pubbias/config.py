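"""Run configuration with YAML (and JSON, a YAML subset) round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulation run.

    ``reps_bias`` / ``reps_no_bias`` are the scaled-down defaults; the
    full-study counts (1,545 / 3,729) can be planned with
    :func:`pubbias.experiment.required_replications` and set here.
    """

    master_seed: int = 0
    reps_bias: int = 200
    reps_no_bias: int = 500
    conditions: list[str] | None = None  # condition-id filter; None = all 100
    alpha: float = 0.05
    caliper_widths: list[float] = field(default_factory=lambda: [0.03, 0.05, 0.10, 0.15])
    caliper_dialect: str = "multiplicative"
    fat_alternative: str = "greater"
    out_dir: str = "results"
    log_level: str = "INFO"

    def reps_for(self, condition) -> int:
        return self.reps_no_bias if condition.intent == 0 else self.reps_bias

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)
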