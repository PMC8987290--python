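"""Run configuration: one YAML-serializable record drives every stage.

All randomness flows from the explicit seeds here; serialize -> parse ->
serialize is bit-identical (sorted keys, plain scalars only).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Tuple

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Configuration for phantom/simulation/cohort/DSS runs."""

    seed: int = 100
    n_cases: int = 20
    grid_n: int = 72
    spacing_mm: float = 2.0
    scenarios: Tuple[str, ...] = ("S0", "S1", "S2", "S3")
    per_section_volume_ml: float = 9.0
    push_min_mm: float = 4.0
    push_max_mm: float = 10.0
    falloff_mm: float = 5.0
    noise_amp: float = 0.0
    n_steps: int = 6
    mesh_step: int = 2
    max_edge_mm: float = 5.0
    smooth_iterations: int = 8
    desired_bed_gy: float = 70.0
    dss_seed: int = 0
    n_draws: int = 10000
    verbosity: str = "info"

    def to_yaml(self) -> str:
        d = asdict(self)
        d["scenarios"] = list(d["scenarios"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "scenarios" in d:
            d["scenarios"] = tuple(d["scenarios"])
        return cls(**d)

    @classmethod
    def load(cls, path: Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def save(self, path: Path) -> None:
        Path(path).write_text(self.to_yaml())

    def cohort_settings(self):
        from . import simulate
        from .cohort import CohortSettings

        return CohortSettings(
            n_cases=self.n_cases,
            base_seed=self.seed,
            grid_n=self.grid_n,
            spacing_mm=self.spacing_mm,
            scenarios=tuple(self.scenarios),
            per_section_volume_ml=self.per_section_volume_ml,
            push_range_mm=(self.push_min_mm, self.push_max_mm),
            falloff_mm=self.falloff_mm,
            noise_amp=self.noise_amp,
            desired_bed_gy=self.desired_bed_gy,
            sim=simulate.SimulationSettings(
                n_steps=self.n_steps,
                mesh_step=self.mesh_step,
                max_edge_mm=self.max_edge_mm,
                smooth_iterations=self.smooth_iterations,
            ),
        )
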