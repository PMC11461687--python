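"""Validated run configuration (YAML) shared by the CLI subcommands.

Unknown keys are rejected for typo safety; every field carries units in
its description and a default matching the package's standard experiment
settings (initial SAA size 100, simulation sample 500, 10 replicates, 5%
optimality tolerance, 1e-4 MIP gap, 1-hour solver time limit).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .instance import ResourcePool, ResourceUnit
from .mco import MCOConfig
from .milp import SolverConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PoolTypeSettings(_Strict):
    name: str
    n_units: int = Field(default=1, ge=1)
    capacity: int | None = Field(
        default=None, ge=1, description="simultaneous activities per unit; None = never binds"
    )


class CohortSettings(_Strict):
    n_patients: int = Field(default=4, ge=1)
    arrival_interval: int = Field(default=10, ge=1, description="minutes")


class MCOSettings(_Strict):
    n0: int = Field(default=100, ge=1, description="initial SAA sample size")
    n_prime: int = Field(default=500, ge=1, description="simulation sample size")
    replicates: int = Field(default=10, ge=1)
    epsilon: float = Field(default=0.05, gt=0.0, lt=1.0)
    growth_factor: int = Field(default=2, ge=2)
    max_iterations: int = Field(default=5, ge=1)

    def to_mco_config(self, master_seed: int) -> MCOConfig:
        return MCOConfig(
            n0=self.n0,
            n_prime=self.n_prime,
            replicates=self.replicates,
            epsilon=self.epsilon,
            growth_factor=self.growth_factor,
            max_iterations=self.max_iterations,
            master_seed=master_seed,
        )


class SolverSettings(_Strict):
    mip_gap: float = Field(default=1e-4, gt=0.0)
    time_limit: float = Field(default=3600.0, gt=0.0, description="seconds per model")
    threads: int = Field(default=1, ge=1)
    big_m: float | None = Field(default=None, gt=0.0)

    def to_solver_config(self) -> SolverConfig:
        return SolverConfig(
            mip_gap=self.mip_gap,
            time_limit=self.time_limit,
            threads=self.threads,
            big_m=self.big_m,
        )


class RunConfig(_Strict):
    cohort: CohortSettings = CohortSettings()
    pool: list[PoolTypeSettings] = Field(
        default_factory=lambda: [
            PoolTypeSettings(name="Intake"),
            PoolTypeSettings(name="Discharge"),
            PoolTypeSettings(name="Radiology Tech", capacity=1),
            PoolTypeSettings(name="Provider", capacity=1),
            PoolTypeSettings(name="Ortho Tech", capacity=1),
        ]
    )
    mco: MCOSettings = MCOSettings()
    solver: SolverSettings = SolverSettings()
    horizon: int = Field(default=240, ge=1, description="minutes")
    seed: int = Field(default=0, ge=0)

    def build_pool(self) -> ResourcePool:
        units: list[ResourceUnit] = []
        for t in self.pool:
            cap = t.capacity if t.capacity is not None else max(1, self.cohort.n_patients)
            for i in range(t.n_units):
                units.append(ResourceUnit(f"{t.name}-{i:02d}", t.name, cap))
        return ResourcePool(units=tuple(units))

    def desk_scale(self) -> bool:
        """Heuristic: is a single SAA solve small enough for a laptop?

        Estimated from the second-stage row count — four sequencing rows
        per shared-type activity pair per scenario, with roughly four
        activities per patient mostly sharing types.
        """
        n_act = self.cohort.n_patients * 4
        est_pairs = n_act * (n_act - 1)
        return est_pairs * 4 * self.mco.n0 <= 200_000


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML configuration; empty file -> pure defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"configuration root must be a mapping, got {type(data)}")
    return RunConfig.model_validate(data)
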