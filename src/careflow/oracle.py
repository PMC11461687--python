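"""Exact brute-force scheduling oracle for tiny instances.

Used only in tests, as an independent cross-check on the MILP: it shares no
code with the model assembly and no solver. The search enumerates every
unit assignment, and for each assignment enumerates schedules in
nondecreasing start-time order where each start is either the activity's
release time or the completion time of an earlier-started activity. For a
regular (start-time-monotone) objective such as total waiting, any schedule
can be left-shifted activity by activity onto such event points without
increasing the objective, so the enumeration contains an optimum. Capacity
is checked at start times, which is exhaustive because unit concurrency
only increases when an activity starts.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np

from .instance import DurationScenario, ProblemInstance

MAX_ORACLE_ACTIVITIES = 14


class HorizonTooSmall(ValueError):
    """No feasible schedule fits in the requested horizon."""


def _assignments(instance: ProblemInstance):
    """Yield one unit-assignment map {activity: (unit ids)} per combination."""
    per_activity = []
    for a in instance.activities:
        options = []
        for rtype, count in sorted(a.requirements.items()):
            units = [u.unit_id for u in instance.pool.units_of(rtype)]
            options.append(list(itertools.combinations(units, count)))
        per_activity.append(
            [sum(combo, ()) for combo in itertools.product(*options)]
        )
    for choice in itertools.product(*per_activity):
        yield {a.index: choice[i] for i, a in enumerate(instance.activities)}


def brute_force_optimum(
    instance: ProblemInstance,
    durations: DurationScenario | np.ndarray,
    horizon: int,
) -> int:
    """Exact minimum total waiting time (minutes) by exhaustive search."""
    n = instance.n_activities
    if n > MAX_ORACLE_ACTIVITIES:
        raise ValueError(
            f"oracle limited to {MAX_ORACLE_ACTIVITIES} activities, got {n}"
        )
    d = np.asarray(
        durations.durations
        if isinstance(durations, DurationScenario)
        else durations,
        dtype=np.int64,
    )
    acts = instance.activities
    capacity = {u.unit_id: u.capacity for u in instance.pool.units}
    release_const = [
        a.scheduled_time if a.is_initial else None for a in acts
    ]
    succ = instance.successor()
    # optimistic per-patient lower bound on the last activity's start
    chain_lb = [0] * n
    for a in acts:
        if a.is_initial:
            chain_lb[a.index] = a.scheduled_time
        else:
            chain_lb[a.index] = chain_lb[a.pre] + int(d[a.pre])
    last_ids = [a.index for a in acts if a.index not in succ]

    best = np.inf
    starts = [-1] * n

    def release(i: int) -> int:
        if release_const[i] is not None:
            return release_const[i]
        p = acts[i].pre
        return starts[p] + int(d[p])

    def feasible_at(i: int, t: int, assign) -> bool:
        for j in assign[i]:
            conc = 1
            for o in range(n):
                if o != i and starts[o] >= 0 and j in assign[o]:
                    if starts[o] <= t < starts[o] + int(d[o]):
                        conc += 1
            if conc > capacity[j]:
                return False
        return True

    def dfs(scheduled: int, t_floor: int, partial: float, assign) -> None:
        nonlocal best
        if partial >= best:
            return
        if scheduled == n:
            best = partial
            return
        for a in acts:
            i = a.index
            if starts[i] >= 0:
                continue
            if a.pre is not None and starts[a.pre] < 0:
                continue
            r = release(i)
            e0 = max(t_floor, r)
            ends = sorted(
                {starts[o] + int(d[o]) for o in range(n) if starts[o] >= 0}
            )
            candidates = [e0] + [e for e in ends if e > e0]
            for t in candidates:
                if t > horizon:
                    continue
                if not feasible_at(i, t, assign):
                    continue
                starts[i] = t
                dfs(scheduled + 1, t, partial + (t - r), assign)
                starts[i] = -1

    for assign in _assignments(instance):
        for i in range(n):
            starts[i] = -1
        dfs(0, 0, 0.0, assign)
    if not np.isfinite(best):
        raise HorizonTooSmall(
            f"no schedule fits in horizon {horizon}; minimal bound is "
            f"{max(chain_lb[i] + int(d[i]) for i in last_ids)}"
        )
    return int(round(best))
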