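"""Monte Carlo Optimization: SAA sample-size search with statistical bounds.

The sample-average optimum over N scenarios is, in expectation, a lower
bound on the true stochastic optimum, while evaluating the resulting fixed
first stage on N' fresh scenarios gives an upper bound. The procedure runs
K independent optimization+simulation replicates, averages both bounds, and
stops once the Approximate Optimality Index

    AOI = |v_bar_N' - v_bar_N| / v_bar_N'

falls below a tolerance ``epsilon``; otherwise N is grown geometrically and
the loop repeats. The final iteration's simulation scenarios are retained
so that the mean-value baseline can be evaluated on the *same* scenario
set, yielding the Value of the Stochastic Solution (VSS).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .instance import (
    DurationScenario,
    ProblemInstance,
    build_instance,
    mean_value_durations,
    sample_cohort,
    sample_scenarios,
    ResourcePool,
)
from .milp import (
    FirstStageSolution,
    SolverConfig,
    evaluate_first_stage,
    solve_deterministic,
    solve_saa,
)
from .pathways import PathwayProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCOConfig:
    """Loop controls. ``n0`` must be far smaller than the simulation sample
    ``n_prime``; ``epsilon`` is the relative optimality tolerance."""

    n0: int = 100
    n_prime: int = 500
    replicates: int = 10
    epsilon: float = 0.05
    growth_factor: int = 2
    max_iterations: int = 5
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if self.n_prime < self.n0:
            raise ValueError("n_prime must be >= n0")
        if not (0.0 < self.epsilon < 1.0):
            raise ValueError("epsilon must lie in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class MCOIteration:
    n: int
    v_opt: list[float]  # per-replicate SAA optima (lower-bound samples)
    v_sim: list[float]  # per-replicate simulation values (upper-bound samples)
    v_bar_opt: float
    v_bar_sim: float
    aoi: float
    opt_seconds: float
    sim_seconds: float


@dataclass
class MCOResult:
    iterations: list[MCOIteration]
    first_stage: FirstStageSolution
    simulation_scenarios: list[list[DurationScenario]]  # per replicate, last iteration
    converged: bool

    @property
    def final(self) -> MCOIteration:
        return self.iterations[-1]


@dataclass
class VSSReport:
    """Stochastic-vs-mean-value comparison on a common scenario set.

    ``vss = v_bar_base - v_bar_sim`` (positive means the stochastic
    solution waits less); ``ratio = vss / v_bar_base`` is the relative
    waiting-time reduction attributable to modelling duration uncertainty.
    """

    v_bar_sim: float
    v_bar_base: float
    vss: float
    ratio: float
    se: float
    per_replicate_sim: list[float] = field(default_factory=list)
    per_replicate_base: list[float] = field(default_factory=list)


def compute_aoi(v_bar_opt: float, v_bar_sim: float) -> float:
    """Relative gap between the statistical bounds; 0 when both vanish."""
    if v_bar_sim < 0:
        raise ValueError("v_bar_sim must be non-negative")
    if v_bar_sim == 0.0:
        if abs(v_bar_opt) < 1e-12:
            return 0.0
        raise ValueError("AOI undefined: v_bar_sim is 0 but v_bar_opt is not")
    return abs(v_bar_sim - v_bar_opt) / v_bar_sim


def run_mco(
    instance: ProblemInstance,
    cfg: MCOConfig | None = None,
    solver_cfg: SolverConfig | None = None,
) -> MCOResult:
    """Run the bound-gap sample-size search.

    Per iteration and replicate, ``N + N'`` i.i.d. scenarios are drawn; the
    SAA is solved on the first ``N`` and its fixed first stage is evaluated
    on the last ``N'``. Replicate seeds derive from the master seed via
    ``numpy`` seed-sequence spawning, so every number is reproducible from
    the configuration alone.
    """
    cfg = cfg or MCOConfig()
    solver_cfg = solver_cfg or SolverConfig()
    root = np.random.SeedSequence(cfg.master_seed)
    n = cfg.n0
    iterations: list[MCOIteration] = []
    best_fs: FirstStageSolution | None = None
    sim_sets: list[list[DurationScenario]] = []
    converged = False
    for it in range(cfg.max_iterations):
        children = root.spawn(cfg.replicates)
        v_opt: list[float] = []
        v_sim: list[float] = []
        fs_list: list[FirstStageSolution] = []
        sim_sets = []
        t_opt = t_sim = 0.0
        for k in range(cfg.replicates):
            rng = np.random.default_rng(children[k])
            scen = sample_scenarios(instance, n + cfg.n_prime, rng)
            opt_scen, sim_scen = scen[: n], scen[n :]
            t0 = time.perf_counter()
            saa = solve_saa(instance, opt_scen, solver_cfg)
            t1 = time.perf_counter()
            ev = evaluate_first_stage(instance, saa.first_stage, sim_scen, solver_cfg)
            t2 = time.perf_counter()
            t_opt += t1 - t0
            t_sim += t2 - t1
            v_opt.append(saa.objective)
            v_sim.append(ev.objective)
            fs_list.append(saa.first_stage)
            sim_sets.append(sim_scen)
        v_bar_opt = float(np.mean(v_opt))
        v_bar_sim = float(np.mean(v_sim))
        aoi = compute_aoi(v_bar_opt, v_bar_sim)
        iterations.append(
            MCOIteration(
                n=n,
                v_opt=v_opt,
                v_sim=v_sim,
                v_bar_opt=v_bar_opt,
                v_bar_sim=v_bar_sim,
                aoi=aoi,
                opt_seconds=t_opt,
                sim_seconds=t_sim,
            )
        )
        # retain the replicate whose simulation value is best
        best_fs = fs_list[int(np.argmin(v_sim))]
        logger.info(
            "MCO iteration %d: N=%d v_bar_N=%.3f v_bar_N'=%.3f AOI=%.4f",
            it,
            n,
            v_bar_opt,
            v_bar_sim,
            aoi,
        )
        if aoi < cfg.epsilon:
            converged = True
            break
        n *= cfg.growth_factor
    else:
        logger.warning("MCO reached max_iterations with AOI >= epsilon")
    assert best_fs is not None
    return MCOResult(
        iterations=iterations,
        first_stage=best_fs,
        simulation_scenarios=sim_sets,
        converged=converged,
    )


def compute_vss(
    instance: ProblemInstance,
    mco: MCOResult,
    solver_cfg: SolverConfig | None = None,
) -> VSSReport:
    """Value of the Stochastic Solution against the mean-value baseline.

    The deterministic model is solved under mean durations; its fixed
    first stage is evaluated on the very scenario sets retained from the
    MCO's final iteration, making the two solutions directly comparable.
    """
    if not mco.simulation_scenarios:
        raise ValueError("MCO result carries no retained simulation scenarios")
    solver_cfg = solver_cfg or SolverConfig()
    det = solve_deterministic(instance, mean_value_durations(instance), solver_cfg)
    per_base = []
    for sim_scen in mco.simulation_scenarios:
        per_base.append(
            evaluate_first_stage(instance, det.first_stage, sim_scen, solver_cfg).objective
        )
    per_sim = mco.final.v_sim
    if len(per_base) != len(per_sim):
        raise ValueError("scenario sets mismatched between MCO and baseline")
    v_bar_base = float(np.mean(per_base))
    v_bar_sim = mco.final.v_bar_sim
    vss = v_bar_base - v_bar_sim
    ratio = vss / v_bar_base if v_bar_base > 0 else 0.0
    diff = np.asarray(per_base) - np.asarray(per_sim)
    se = float(diff.std(ddof=1) / np.sqrt(len(diff))) if len(diff) > 1 else 0.0
    return VSSReport(
        v_bar_sim=v_bar_sim,
        v_bar_base=v_bar_base,
        vss=vss,
        ratio=ratio,
        se=se,
        per_replicate_sim=list(per_sim),
        per_replicate_base=per_base,
    )


def run_experiment_grid(
    profiles: Sequence[PathwayProfile],
    n_patients_list: Sequence[int],
    interval_list: Sequence[int],
    capacity_configs: Sequence[dict] | None = None,
    mco_cfg: MCOConfig | None = None,
    solver_cfg: SolverConfig | None = None,
    seed: int = 0,
    horizon: int = 240,
):
    """Sweep (cohort size, arrival interval, capacity config) cells.

    For each cell a cohort is sampled, the instance built, the MCO run and
    the VSS computed; one result row is emitted per cell. Per-cell solver
    failures are recorded in the row and the grid continues.
    """
    import pandas as pd

    capacity_configs = list(capacity_configs or [{}])
    mco_cfg = mco_cfg or MCOConfig()
    solver_cfg = solver_cfg or SolverConfig()
    root = np.random.SeedSequence(seed)
    rows = []
    cells = [
        (n_p, iv, ci)
        for n_p in n_patients_list
        for iv in interval_list
        for ci in range(len(capacity_configs))
    ]
    cell_seeds = root.spawn(len(cells))
    for (n_p, iv, ci), cell_seed in zip(cells, cell_seeds):
        cap = capacity_configs[ci]
        row = {
            "n_patients": n_p,
            "interval": iv,
            "capacity_config": ci,
            "seed_entropy": int(cell_seed.generate_state(1)[0]),
        }
        try:
            cohort_seed, mco_seed = cell_seed.spawn(2)
            cohort = sample_cohort(
                profiles, n_p, iv, np.random.default_rng(cohort_seed)
            )
            pool = ResourcePool.clinic_default(
                n_p,
                bottleneck_units=cap.get("units"),
                bottleneck_capacity=cap.get("capacity"),
            )
            inst = build_instance(cohort, profiles, pool, horizon=horizon)
            cell_mco_cfg = MCOConfig(
                n0=mco_cfg.n0,
                n_prime=mco_cfg.n_prime,
                replicates=mco_cfg.replicates,
                epsilon=mco_cfg.epsilon,
                growth_factor=mco_cfg.growth_factor,
                max_iterations=mco_cfg.max_iterations,
                master_seed=int(mco_seed.generate_state(1)[0] % (2**31)),
            )
            mco = run_mco(inst, cell_mco_cfg, solver_cfg)
            vss = compute_vss(inst, mco, solver_cfg)
            row.update(
                vss=vss.vss,
                ratio=vss.ratio,
                v_bar_sim=vss.v_bar_sim,
                v_bar_base=vss.v_bar_base,
                aoi=mco.final.aoi,
                n_final=mco.final.n,
                converged=mco.converged,
                opt_seconds=mco.final.opt_seconds,
                error="",
            )
        except Exception as exc:  # noqa: BLE001 - grid must continue
            logger.exception("grid cell (%s, %s, %s) failed", n_p, iv, ci)
            row.update(
                vss=np.nan,
                ratio=np.nan,
                v_bar_sim=np.nan,
                v_bar_base=np.nan,
                aoi=np.nan,
                n_final=0,
                converged=False,
                opt_seconds=np.nan,
                error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)
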