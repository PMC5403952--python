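"""Pipeline configuration: one YAML/JSON file governing all stages."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .synth import CohortProfile, default_profiles

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything a reproducible three-phase run needs.

    A seed is mandatory: every stochastic stage (cohort generation, split
    drawing, weight initialization, restarts) derives its stream from it.
    """

    seed: int
    output_dir: str = "cyclogait_output"
    trials_path: str | None = None  # None -> generate synthetic cohorts
    side: str = "left"
    n_normal_subjects: int = 10
    n_subjects_per_cohort: int = 5
    n_trials: int = 10
    mse_max: float = 0.9
    r_min: float = 0.9
    val_test_ratio: float = 0.5
    max_restarts: int = 10
    tie_tolerance: float = 0.05
    neighbor_tolerance: float = 0.05
    profiles: dict = field(default_factory=dict)  # overrides of the defaults
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for every stochastic stage")
        self.seed = int(self.seed)
        for name in ("mse_max", "r_min", "val_test_ratio", "tie_tolerance",
                     "neighbor_tolerance"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    def cohort_profiles(self) -> dict[str, CohortProfile]:
        """Default profiles with any config-file overrides applied."""
        profiles = default_profiles()
        for name, override in self.profiles.items():
            override = dict(override)
            override.setdefault("cohort", name)
            profiles[name] = CohortProfile.from_dict(override)
        return profiles

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if "seed" not in data:
            raise ValueError(f"config {path} must set a seed")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = asdict(self)
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data))
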