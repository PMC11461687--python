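"""Two-stage stochastic MILP for multi-resource allocation and sequencing.

The model assigns each care activity to concrete resource units and fixes a
pairwise sequencing plan before activity durations are known (first stage),
then chooses per-scenario start times that minimize total patient waiting
(second stage). Decision variables:

``x[a,j]``
    binary: unit ``j`` serves activity ``a`` (only where ``a`` requires
    ``j``'s type).
``s1[a,a']``
    binary: activity ``a`` does not start before ``a'`` starts.
``s2[a,a']``
    binary: activity ``a`` starts before ``a'`` ends. Both sequencing
    indicators exist only for ordered pairs of distinct activities sharing
    at least one required resource type.
``q[a,a',j]``
    binary concurrency indicator, lower-bounded by
    ``s1 + s2 + x[a,j] + x[a',j] - 3``; summing it over ``a'`` and capping
    at ``k_j - 1`` enforces unit capacities at activity start times (which
    suffices, since concurrency on a unit only increases at starts).
``b[a]`` (per scenario)
    continuous start time in minutes.

Sequencing uses big-M disjunctions with a one-minute strictness constant;
no time-indexed or rank-indexed variables appear, so model size is
independent of the horizon. Under the sample average approximation the
second stage is replicated once per sampled duration scenario with shared
first-stage binaries, and the objective is the scenario-average total
waiting time.

The solver backend is HiGHS through :func:`scipy.optimize.milp`
(:func:`scipy.optimize.linprog` for the fixed-first-stage evaluation LPs);
solutions carry the solver's relative MIP gap rather than an assumed
optimality certificate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .instance import Activity, DurationScenario, ProblemInstance

logger = logging.getLogger(__name__)

_BIN_TOL = 1e-6


@dataclass(frozen=True)
class SolverConfig:
    """Backend settings; the default big-M rule is
    ``M = max_a t_a + sum_a d_a^max + 1`` computed per scenario set, the
    smallest easily-provable constant that keeps every relaxed disjunction
    slack."""

    mip_gap: float = 1e-4
    time_limit: float = 3600.0
    threads: int = 1  # accepted for API compatibility; HiGHS-via-scipy is single-threaded
    big_m: float | None = None
    backend: str = "highs"
    seed: int | None = None


@dataclass(frozen=True)
class FirstStageSolution:
    """Fixed assignment and sequencing plan (all first-stage binaries)."""

    x: Mapping[tuple[int, str], int]
    s1: Mapping[tuple[int, int], int]
    s2: Mapping[tuple[int, int], int]
    q: Mapping[tuple[int, int, str], int]

    def assigned_units(self, a: int) -> tuple[str, ...]:
        return tuple(sorted(j for (ai, j), v in self.x.items() if ai == a and v))


@dataclass(frozen=True)
class ScheduleRealization:
    """Second-stage outcome for one duration scenario."""

    scenario_index: int
    start_times: np.ndarray
    waits: np.ndarray
    objective: float
    relaxed_pairs: tuple[tuple[int, int], ...] = ()


@dataclass
class SAAResult:
    first_stage: FirstStageSolution
    realizations: list[ScheduleRealization]
    objective: float
    optimal: bool
    mip_gap: float


@dataclass
class EvaluationResult:
    realizations: list[ScheduleRealization]
    objective: float

    @property
    def relaxed_scenarios(self) -> list[int]:
        return [r.scenario_index for r in self.realizations if r.relaxed_pairs]


@dataclass
class FeasibilityReport:
    """Independent constraint audit; ``feasible`` iff all lists are empty."""

    assignment: list[str] = field(default_factory=list)
    concurrency: list[str] = field(default_factory=list)
    capacity: list[str] = field(default_factory=list)
    release: list[str] = field(default_factory=list)
    precedence: list[str] = field(default_factory=list)
    sequencing: list[str] = field(default_factory=list)

    @property
    def feasible(self) -> bool:
        return not (
            self.assignment
            or self.concurrency
            or self.capacity
            or self.release
            or self.precedence
            or self.sequencing
        )


class SolverFailure(RuntimeError):
    """The backend produced no usable incumbent."""


# ---------------------------------------------------------------------------
# Model structure
# ---------------------------------------------------------------------------


class ModelStructure:
    """Index maps shared by the SAA model and the evaluation LPs."""

    def __init__(self, instance: ProblemInstance):
        self.instance = instance
        acts = instance.activities
        pool = instance.pool
        self.unit_ids = [u.unit_id for u in pool.units]
        self.unit_index = {u.unit_id: i for i, u in enumerate(pool.units)}
        self.capacity = {u.unit_id: u.capacity for u in pool.units}
        self.req_types = [set(a.requirements) for a in acts]

        # x variables: (activity, unit) with the unit's type required by a
        self.x_keys: list[tuple[int, str]] = []
        for a in acts:
            for rtype in a.requirements:
                for u in pool.units_of(rtype):
                    self.x_keys.append((a.index, u.unit_id))
        # ordered activity pairs sharing >= 1 required type
        self.pair_keys: list[tuple[int, int]] = []
        n = len(acts)
        for a in range(n):
            for ap in range(n):
                if a != ap and self.req_types[a] & self.req_types[ap]:
                    self.pair_keys.append((a, ap))
        # q triples: pair plus a unit whose type both activities require
        self.triple_keys: list[tuple[int, int, str]] = []
        for a, ap in self.pair_keys:
            shared = self.req_types[a] & self.req_types[ap]
            for rtype in sorted(shared):
                for u in pool.units_of(rtype):
                    self.triple_keys.append((a, ap, u.unit_id))

        self.nx = len(self.x_keys)
        self.ns = len(self.pair_keys)
        self.nq = len(self.triple_keys)
        self.x_index = {k: i for i, k in enumerate(self.x_keys)}
        self.pair_index = {k: i for i, k in enumerate(self.pair_keys)}
        self.triple_index = {k: i for i, k in enumerate(self.triple_keys)}
        # objective weight: 1 for each patient's last activity, else 0
        succ = instance.successor()
        self.last_weight = np.array(
            [0.0 if a.index in succ else 1.0 for a in acts]
        )

    def default_big_m(self, d_matrix: np.ndarray) -> float:
        t_max = max(
            (a.scheduled_time or 0) for a in self.instance.activities
        )
        return float(t_max + d_matrix.max(axis=0).sum() + 1)


def _as_matrix(scenarios: Sequence[DurationScenario]) -> np.ndarray:
    return np.vstack([np.asarray(s.durations, dtype=np.int64) for s in scenarios])


# ---------------------------------------------------------------------------
# SAA model assembly and solve
# ---------------------------------------------------------------------------


def _assemble(
    st: ModelStructure, d: np.ndarray, cfg: SolverConfig
) -> dict:
    inst = st.instance
    acts = inst.activities
    n_act = len(acts)
    n_scen = d.shape[0]
    nx, ns, nq = st.nx, st.ns, st.nq
    off_s1 = nx
    off_s2 = nx + ns
    off_q = nx + 2 * ns
    off_b = nx + 2 * ns + nq
    n_var = off_b + n_scen * n_act
    M = cfg.big_m if cfg.big_m is not None else st.default_big_m(d)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    lo: list[float] = []
    hi: list[float] = []
    r = 0

    def add(entries, lb, ub):
        nonlocal r
        for c, v in entries:
            rows.append(r)
            cols.append(c)
            vals.append(v)
        lo.append(lb)
        hi.append(ub)
        r += 1

    # (1b) assignment: sum_{j in J_g} x[a,j] = V_{a,g}
    for a in acts:
        for rtype, count in a.requirements.items():
            entries = [
                (st.x_index[(a.index, u.unit_id)], 1.0)
                for u in inst.pool.units_of(rtype)
            ]
            add(entries, float(count), float(count))
    # (1c) concurrency linkage: q >= s1 + s2 + x_a + x_a' - 3
    for t_i, (a, ap, j) in enumerate(st.triple_keys):
        p = st.pair_index[(a, ap)]
        add(
            [
                (off_q + t_i, 1.0),
                (off_s1 + p, -1.0),
                (off_s2 + p, -1.0),
                (st.x_index[(a, j)], -1.0),
                (st.x_index[(ap, j)], -1.0),
            ],
            -3.0,
            np.inf,
        )
    # (1d) capacity: sum_{a'} q[a,a',j] <= k_j - 1
    by_aj: dict[tuple[int, str], list[int]] = {}
    for t_i, (a, ap, j) in enumerate(st.triple_keys):
        by_aj.setdefault((a, j), []).append(t_i)
    for (a, j), t_list in sorted(by_aj.items()):
        add(
            [(off_q + t_i, 1.0) for t_i in t_list],
            -np.inf,
            float(st.capacity[j] - 1),
        )
    # second stage, replicated per scenario
    for n in range(n_scen):
        bcol = lambda a_idx: off_b + n * n_act + a_idx
        # (2c) precedence (releases (2b) are handled via variable bounds)
        for a in acts:
            if a.pre is not None:
                add(
                    [(bcol(a.index), 1.0), (bcol(a.pre), -1.0)],
                    float(d[n, a.pre]),
                    np.inf,
                )
        for p, (a, ap) in enumerate(st.pair_keys):
            da_p = float(d[n, ap])
            # (2d)  b_a - b_a' - M s1 <= -1
            add(
                [(bcol(a), 1.0), (bcol(ap), -1.0), (off_s1 + p, -M)],
                -np.inf,
                -1.0,
            )
            # (2e)  b_a' - b_a + M s1 <= M
            add(
                [(bcol(ap), 1.0), (bcol(a), -1.0), (off_s1 + p, M)],
                -np.inf,
                M,
            )
            # (2f)  b_a' - b_a - M s2 <= -d_a'
            add(
                [(bcol(ap), 1.0), (bcol(a), -1.0), (off_s2 + p, -M)],
                -np.inf,
                -da_p,
            )
            # (2g)  b_a - b_a' + M s2 <= M + d_a' - 1
            add(
                [(bcol(a), 1.0), (bcol(ap), -1.0), (off_s2 + p, M)],
                -np.inf,
                M + da_p - 1.0,
            )

    A = sparse.csr_array(
        (vals, (rows, cols)), shape=(r, n_var), dtype=float
    )
    c = np.zeros(n_var)
    for n in range(n_scen):
        c[off_b + n * n_act : off_b + (n + 1) * n_act] = st.last_weight / n_scen
    lb = np.zeros(n_var)
    ub = np.full(n_var, np.inf)
    ub[:off_b] = 1.0
    for a in acts:
        if a.is_initial:
            for n in range(n_scen):
                lb[off_b + n * n_act + a.index] = float(a.scheduled_time)
    integrality = np.zeros(n_var)
    integrality[:off_b] = 1.0
    return {
        "A": A,
        "row_lo": np.array(lo),
        "row_hi": np.array(hi),
        "c": c,
        "lb": lb,
        "ub": ub,
        "integrality": integrality,
        "off": (0, off_s1, off_s2, off_q, off_b),
        "big_m": M,
        "n_scen": n_scen,
        "n_act": n_act,
    }


def _waits(
    inst: ProblemInstance, b: np.ndarray, d: np.ndarray
) -> np.ndarray:
    w = np.empty(len(inst.activities))
    for a in inst.activities:
        if a.pre is None:
            w[a.index] = b[a.index] - a.scheduled_time
        else:
            w[a.index] = b[a.index] - b[a.pre] - d[a.pre]
    return w


def _extract_first_stage(
    st: ModelStructure, z: np.ndarray, off: tuple
) -> FirstStageSolution:
    _, off_s1, off_s2, off_q, _ = off
    rb = lambda v: int(round(v))
    return FirstStageSolution(
        x={k: rb(z[i]) for i, k in enumerate(st.x_keys)},
        s1={k: rb(z[off_s1 + i]) for i, k in enumerate(st.pair_keys)},
        s2={k: rb(z[off_s2 + i]) for i, k in enumerate(st.pair_keys)},
        q={k: rb(z[off_q + i]) for i, k in enumerate(st.triple_keys)},
    )


def solve_saa(
    instance: ProblemInstance,
    scenarios: Sequence[DurationScenario],
    cfg: SolverConfig | None = None,
) -> SAAResult:
    """Solve the sample-average approximation over the given scenarios.

    First-stage constraints appear once; the second-stage start-time model
    is replicated per scenario with shared binaries. Returns the first
    stage, per-scenario realizations, and the scenario-average objective
    ``v_N``. If the time limit binds, the best incumbent is returned with
    ``optimal=False``; with no incumbent a :class:`SolverFailure` is raised.
    """
    if not scenarios:
        raise ValueError("need at least one scenario")
    cfg = cfg or SolverConfig()
    st = ModelStructure(instance)
    d = _as_matrix(scenarios)
    model = _assemble(st, d, cfg)
    res = milp(
        c=model["c"],
        constraints=LinearConstraint(model["A"], model["row_lo"], model["row_hi"]),
        integrality=model["integrality"],
        bounds=Bounds(model["lb"], model["ub"]),
        options={
            "mip_rel_gap": cfg.mip_gap,
            "time_limit": cfg.time_limit,
            "presolve": True,
        },
    )
    if res.status == 2:
        raise SolverFailure(
            "model reported infeasible; this cannot occur for a valid "
            "instance — dump the model with write_lp_dump for debugging"
        )
    if res.x is None:
        raise SolverFailure(f"no incumbent found (status {res.status})")
    z = res.x
    off_b = model["off"][4]
    n_act = model["n_act"]
    realizations = []
    objs = []
    for n in range(len(scenarios)):
        b = z[off_b + n * n_act : off_b + (n + 1) * n_act]
        w = _waits(instance, b, d[n])
        realizations.append(
            ScheduleRealization(
                scenario_index=scenarios[n].index,
                start_times=b.copy(),
                waits=w,
                objective=float(w.sum()),
            )
        )
        objs.append(w.sum())
    gap = float(res.mip_gap) if res.mip_gap is not None else np.nan
    return SAAResult(
        first_stage=_extract_first_stage(st, z, model["off"]),
        realizations=realizations,
        objective=float(np.mean(objs)),
        optimal=bool(res.status == 0),
        mip_gap=gap,
    )


def solve_deterministic(
    instance: ProblemInstance,
    durations: DurationScenario,
    cfg: SolverConfig | None = None,
) -> SAAResult:
    """Deterministic counterpart: the SAA model with a single scenario."""
    return solve_saa(instance, [durations], cfg)


# ---------------------------------------------------------------------------
# Fixed-first-stage evaluation
# ---------------------------------------------------------------------------


def validate_first_stage(
    instance: ProblemInstance, fs: FirstStageSolution
) -> None:
    """Reject a first stage violating assignment, linkage or capacity."""
    st = ModelStructure(instance)
    for a in instance.activities:
        for rtype, count in a.requirements.items():
            total = sum(
                fs.x.get((a.index, u.unit_id), 0)
                for u in instance.pool.units_of(rtype)
            )
            if total != count:
                raise ValueError(
                    f"assignment count for activity {a.index}, type "
                    f"{rtype!r} is {total}, expected {count}"
                )
    for (a, ap, j) in st.triple_keys:
        lb = (
            fs.s1[(a, ap)]
            + fs.s2[(a, ap)]
            + fs.x[(a, j)]
            + fs.x[(ap, j)]
            - 3
        )
        if fs.q[(a, ap, j)] < lb:
            raise ValueError(f"concurrency linkage violated at {(a, ap, j)}")
    by_aj: dict[tuple[int, str], int] = {}
    for (a, ap, j), v in fs.q.items():
        by_aj[(a, j)] = by_aj.get((a, j), 0) + v
    for (a, j), total in by_aj.items():
        if total > st.capacity[j] - 1:
            raise ValueError(f"capacity exceeded for unit {j!r} at activity {a}")


def _evaluate_one(
    instance: ProblemInstance,
    st: ModelStructure,
    fs: FirstStageSolution,
    scenario: DurationScenario,
) -> ScheduleRealization:
    acts = instance.activities
    n_act = len(acts)
    d = np.asarray(scenario.durations)
    rows, cols, vals, rhs, tags = [], [], [], [], []

    def add(entries, ub, tag=None):
        i = len(rhs)
        for c_, v_ in entries:
            rows.append(i)
            cols.append(c_)
            vals.append(v_)
        rhs.append(ub)
        tags.append(tag)

    for a in acts:
        if a.pre is not None:  # (2c): b_pre - b_a <= -d_pre
            add([(a.pre, 1.0), (a.index, -1.0)], -float(d[a.pre]))
    for (a, ap) in st.pair_keys:
        if fs.s1[(a, ap)]:
            add([(ap, 1.0), (a, -1.0)], 0.0)  # b_a >= b_a'
        else:
            add([(a, 1.0), (ap, -1.0)], -1.0)  # b_a' >= b_a + 1
        if fs.s2[(a, ap)]:
            # planned overlap: a starts strictly before a' ends (relaxable)
            add([(a, 1.0), (ap, -1.0)], float(d[ap]) - 1.0, (a, ap))
        else:
            add([(ap, 1.0), (a, -1.0)], -float(d[ap]))  # b_a >= b_a' + d_a'

    lb = np.array(
        [float(a.scheduled_time) if a.is_initial else 0.0 for a in acts]
    )
    n_rows = len(rhs)
    A = sparse.csr_array(
        (vals, (rows, cols)), shape=(n_rows, n_act), dtype=float
    )
    bounds = list(zip(lb, [None] * n_act))
    res = linprog(
        st.last_weight, A_ub=A, b_ub=np.array(rhs), bounds=bounds, method="highs"
    )
    relaxed: tuple[tuple[int, int], ...] = ()
    if res.status == 2:
        # A planned overlap (s2 = 1) clashes with precedence under the new
        # durations. Find the offending pairs with elastic slacks and drop
        # their constraints only: starting later than planned can only
        # reduce concurrency, so the capacity plan stays safe.
        relax_rows = [i for i, t in enumerate(tags) if t is not None]
        n_slack = len(relax_rows)
        A2 = sparse.hstack(
            [A, sparse.csr_array((n_rows, n_slack), dtype=float)]
        ).tolil()
        for k, i in enumerate(relax_rows):
            A2[i, n_act + k] = -1.0
        c2 = np.concatenate([np.zeros(n_act), np.ones(n_slack)])
        res2 = linprog(
            c2,
            A_ub=A2.tocsr(),
            b_ub=np.array(rhs),
            bounds=bounds + [(0, None)] * n_slack,
            method="highs",
        )
        if res2.status != 0:
            raise SolverFailure("elastic relaxation LP failed")
        offending = [
            tags[i]
            for k, i in enumerate(relax_rows)
            if res2.x[n_act + k] > 1e-7
        ]
        relaxed = tuple(offending)
        keep = [
            i for i in range(n_rows) if tags[i] is None or tags[i] not in offending
        ]
        res = linprog(
            st.last_weight,
            A_ub=A[keep],
            b_ub=np.array(rhs)[keep],
            bounds=bounds,
            method="highs",
        )
        logger.info(
            "scenario %d: dropped planned-overlap constraints for pairs %s",
            scenario.index,
            relaxed,
        )
    if res.status != 0:
        raise SolverFailure(f"evaluation LP failed with status {res.status}")
    b = res.x
    w = _waits(instance, b, d)
    return ScheduleRealization(
        scenario_index=scenario.index,
        start_times=b.copy(),
        waits=w,
        objective=float(w.sum()),
        relaxed_pairs=relaxed,
    )


def evaluate_first_stage(
    instance: ProblemInstance,
    first_stage: FirstStageSolution,
    scenarios: Sequence[DurationScenario],
    cfg: SolverConfig | None = None,
) -> EvaluationResult:
    """Evaluate a fixed first stage on fresh scenarios.

    With all binaries fixed each scenario decouples into a small start-time
    LP. If a scenario is infeasible because a planned overlap (``s2 = 1``)
    clashes with precedence under the realized durations, the overlap
    constraint is dropped for the offending pairs only and the scenario is
    marked relaxed.
    """
    validate_first_stage(instance, first_stage)
    st = ModelStructure(instance)
    realizations = [
        _evaluate_one(instance, st, first_stage, s) for s in scenarios
    ]
    return EvaluationResult(
        realizations=realizations,
        objective=float(np.mean([r.objective for r in realizations])),
    )


# ---------------------------------------------------------------------------
# Independent feasibility audit
# ---------------------------------------------------------------------------


def check_schedule(
    instance: ProblemInstance,
    x: Mapping[tuple[int, str], int] | FirstStageSolution,
    b: np.ndarray,
    durations: DurationScenario | np.ndarray,
    tol: float = 1e-6,
) -> FeasibilityReport:
    """Audit a schedule without trusting the solver's indicator variables.

    Verifies assignment counts, release times, precedence, and — by direct
    interval arithmetic — that at every activity start each assigned unit
    serves at most ``k_j`` concurrent activities. Checking concurrency at
    start times only is sufficient because concurrency on a unit increases
    only when an activity starts.
    """
    if isinstance(x, FirstStageSolution):
        x = x.x
    d = np.asarray(
        durations.durations
        if isinstance(durations, DurationScenario)
        else durations
    )
    rep = FeasibilityReport()
    for a in instance.activities:
        for rtype, count in a.requirements.items():
            units = instance.pool.units_of(rtype)
            total = sum(x.get((a.index, u.unit_id), 0) for u in units)
            if total != count:
                rep.assignment.append(
                    f"activity {a.index}: {total} unit(s) of {rtype!r}, "
                    f"expected {count}"
                )
        if a.is_initial:
            if b[a.index] < a.scheduled_time - tol:
                rep.release.append(
                    f"activity {a.index} starts at {b[a.index]:.3f} before "
                    f"its scheduled time {a.scheduled_time}"
                )
        else:
            lbnd = b[a.pre] + d[a.pre]
            if b[a.index] < lbnd - tol:
                rep.precedence.append(
                    f"activity {a.index} starts at {b[a.index]:.3f} before "
                    f"predecessor completion {lbnd:.3f}"
                )
    assigned: dict[str, list[int]] = {}
    for (a_idx, j), v in x.items():
        if v:
            assigned.setdefault(j, []).append(a_idx)
    for j, act_list in sorted(assigned.items()):
        k_j = next(u.capacity for u in instance.pool.units if u.unit_id == j)
        for a_idx in act_list:
            t0 = b[a_idx]
            conc = sum(
                1
                for o in act_list
                if b[o] <= t0 + tol and t0 < b[o] + d[o] - tol
            )
            if conc > k_j:
                rep.capacity.append(
                    f"unit {j!r} serves {conc} activities at time {t0:.3f} "
                    f"(capacity {k_j})"
                )
    return rep


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def schedule_frame(
    instance: ProblemInstance,
    first_stage: FirstStageSolution,
    realization: ScheduleRealization,
    durations: DurationScenario,
):
    """Delimited schedule table (one row per activity) for a realization."""
    import pandas as pd

    d = np.asarray(durations.durations)
    rows = []
    for a in instance.activities:
        rows.append(
            {
                "activity": a.index,
                "patient": a.patient_id,
                "position": a.position,
                "assigned_units": "|".join(first_stage.assigned_units(a.index)),
                "scenario": realization.scenario_index,
                "start": realization.start_times[a.index],
                "duration": int(d[a.index]),
                "wait": realization.waits[a.index],
            }
        )
    return pd.DataFrame(rows)


def plot_gantt(
    instance: ProblemInstance,
    first_stage: FirstStageSolution,
    realization: ScheduleRealization,
    durations: DurationScenario,
    path,
) -> None:
    """Static Gantt chart: one lane per resource unit, bars per activity."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = np.asarray(durations.durations)
    lanes = {u.unit_id: i for i, u in enumerate(instance.pool.units)}
    fig, ax = plt.subplots(figsize=(10, 0.6 * len(lanes) + 1.5))
    cmap = plt.get_cmap("tab10")
    for a in instance.activities:
        for j in first_stage.assigned_units(a.index):
            ax.barh(
                lanes[j],
                d[a.index],
                left=realization.start_times[a.index],
                height=0.6,
                color=cmap(a.patient_id % 10),
                edgecolor="black",
                linewidth=0.5,
            )
            ax.text(
                realization.start_times[a.index] + d[a.index] / 2,
                lanes[j],
                f"P{a.patient_id}",
                ha="center",
                va="center",
                fontsize=7,
            )
    ax.set_yticks(list(lanes.values()), list(lanes.keys()))
    ax.set_xlabel("minutes from session start")
    ax.set_title(f"schedule, scenario {realization.scenario_index}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_lp_dump(
    instance: ProblemInstance,
    scenarios: Sequence[DurationScenario],
    cfg: SolverConfig,
    path,
) -> None:
    """Write the assembled SAA model in CPLEX-LP text format for debugging."""
    st = ModelStructure(instance)
    model = _assemble(st, _as_matrix(scenarios), cfg or SolverConfig())
    off_b = model["off"][4]
    n_act = model["n_act"]

    def vname(i: int) -> str:
        if i < st.nx:
            a, j = st.x_keys[i]
            return f"x_{a}_{j.replace(' ', '').replace('-', '_')}"
        if i < st.nx + st.ns:
            a, ap = st.pair_keys[i - st.nx]
            return f"s1_{a}_{ap}"
        if i < st.nx + 2 * st.ns:
            a, ap = st.pair_keys[i - st.nx - st.ns]
            return f"s2_{a}_{ap}"
        if i < off_b:
            a, ap, j = st.triple_keys[i - st.nx - 2 * st.ns]
            return f"q_{a}_{ap}_{j.replace(' ', '').replace('-', '_')}"
        k = i - off_b
        return f"b_{k // n_act}_{k % n_act}"

    A = model["A"].tocoo()
    terms: dict[int, list[str]] = {}
    for r_, c_, v_ in zip(A.row, A.col, A.data):
        terms.setdefault(int(r_), []).append(f"{v_:+g} {vname(int(c_))}")
    with open(path, "w") as fh:
        fh.write("Minimize\n obj: ")
        fh.write(
            " ".join(
                f"{v:+g} {vname(i)}" for i, v in enumerate(model["c"]) if v
            )
            or "0"
        )
        fh.write("\nSubject To\n")
        for i in range(len(model["row_lo"])):
            expr = " ".join(terms.get(i, ["0"]))
            lo_, hi_ = model["row_lo"][i], model["row_hi"][i]
            if lo_ == hi_:
                fh.write(f" c{i}: {expr} = {lo_:g}\n")
            else:
                if np.isfinite(lo_):
                    fh.write(f" c{i}l: {expr} >= {lo_:g}\n")
                if np.isfinite(hi_):
                    fh.write(f" c{i}u: {expr} <= {hi_:g}\n")
        fh.write("Bounds\n")
        for i, (l_, u_) in enumerate(zip(model["lb"], model["ub"])):
            ub_txt = f"{u_:g}" if np.isfinite(u_) else "+inf"
            fh.write(f" {l_:g} <= {vname(i)} <= {ub_txt}\n")
        fh.write("Binaries\n ")
        fh.write(" ".join(vname(i) for i in range(off_b)))
        fh.write("\nEnd\n")
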