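"""Build optimization instances from pathway profiles and sample scenarios.

An instance collects, for one clinic session, the activity set ``A``
(partitioned into each patient's initial activity ``A0`` and the subsequent
ones ``A1``), the per-patient precedence chains ``pre(a)``, the
activity-to-resource-type requirement matrix ``V``, the heterogeneous
resource pool with per-unit capacities ``k_j``, and the scheduled times
``t_a`` of the initial activities. Activity durations are random; scenarios
are integer-minute realizations drawn from per-activity log-normal models.
All times are integer minutes from the start of the session horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .pathways import LogNormalParams, PathwayProfile


# ---------------------------------------------------------------------------
# Resource pool
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResourceUnit:
    """One capacitated resource unit (a staff member or device).

    ``capacity`` is the number of activities the unit can serve
    simultaneously (a technician may supervise several patients at once).
    """

    unit_id: str
    rtype: str
    capacity: int

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise ValueError(f"unit {self.unit_id}: capacity must be >= 1")


@dataclass(frozen=True)
class ResourcePool:
    units: tuple[ResourceUnit, ...]

    def __post_init__(self) -> None:
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            raise ValueError("unit ids must be unique across the pool")

    @property
    def types(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for u in self.units:
            seen.setdefault(u.rtype)
        return tuple(seen)

    def units_of(self, rtype: str) -> tuple[ResourceUnit, ...]:
        return tuple(u for u in self.units if u.rtype == rtype)

    @classmethod
    def clinic_default(
        cls,
        n_patients: int,
        bottleneck_units: Mapping[str, int] | None = None,
        bottleneck_capacity: Mapping[str, int] | None = None,
    ) -> "ResourcePool":
        """Default pool for the orthopedics-clinic pathways.

        Radiology Tech, Provider and Ortho Tech are the capacitated
        bottlenecks (one unit of capacity 1 each unless overridden); the
        Intake and Discharge stations get capacity ``n_patients`` so they
        never bind.
        """
        bottleneck_units = dict(bottleneck_units or {})
        bottleneck_capacity = dict(bottleneck_capacity or {})
        units: list[ResourceUnit] = []
        for rtype in ("Intake", "Discharge"):
            units.append(ResourceUnit(f"{rtype}-00", rtype, max(1, n_patients)))
        for rtype in ("Radiology Tech", "Provider", "Ortho Tech"):
            n = bottleneck_units.get(rtype, 1)
            k = bottleneck_capacity.get(rtype, 1)
            for i in range(n):
                units.append(ResourceUnit(f"{rtype}-{i:02d}", rtype, k))
        return cls(units=tuple(units))


# ---------------------------------------------------------------------------
# Cohort and activities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientVisit:
    """One scheduled patient: pathway choice plus appointment time."""

    patient_id: int
    path_id: int
    scheduled_time: int

    def __post_init__(self) -> None:
        if self.scheduled_time < 0:
            raise ValueError("scheduled_time must be >= 0")


@dataclass(frozen=True)
class Activity:
    """One care activity of one patient.

    ``requirements`` maps resource-type label to the number of units
    needed (the row of the requirement matrix V). ``pre`` is the index of
    the immediate predecessor, or ``None`` for a patient's initial
    activity, in which case ``scheduled_time`` is set.
    """

    index: int
    patient_id: int
    position: int
    requirements: Mapping[str, int]
    pre: int | None
    scheduled_time: int | None
    duration_mean: float
    duration_variance: float

    @property
    def is_initial(self) -> bool:
        return self.pre is None


@dataclass(frozen=True)
class DurationScenario:
    """One integer-minute realization of all activity durations."""

    durations: np.ndarray
    index: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.durations)
        if d.size and (d < 1).any():
            raise ValueError("all durations must be >= 1 minute")
        if d.size and not np.issubdtype(d.dtype, np.integer):
            raise ValueError("durations must be integers")


@dataclass(frozen=True)
class ProblemInstance:
    activities: tuple[Activity, ...]
    pool: ResourcePool
    horizon: int = 240

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_activities(self) -> int:
        return len(self.activities)

    @property
    def initial_activities(self) -> tuple[Activity, ...]:
        return tuple(a for a in self.activities if a.is_initial)

    @property
    def patients(self) -> tuple[int, ...]:
        seen: dict[int, None] = {}
        for a in self.activities:
            seen.setdefault(a.patient_id)
        return tuple(seen)

    def chain(self, patient_id: int) -> tuple[Activity, ...]:
        return tuple(
            sorted(
                (a for a in self.activities if a.patient_id == patient_id),
                key=lambda a: a.position,
            )
        )

    def successor(self) -> dict[int, int]:
        """Map activity index -> index of its immediate successor."""
        return {
            a.pre: a.index for a in self.activities if a.pre is not None
        }

    def validate(self) -> None:
        for i, a in enumerate(self.activities):
            if a.index != i:
                raise ValueError("activity indices must be 0..n-1 in order")
            if not a.requirements or all(v == 0 for v in a.requirements.values()):
                raise ValueError(f"activity {i} requires no resource")
            for rtype, count in a.requirements.items():
                avail = len(self.pool.units_of(rtype))
                if count > avail:
                    raise ValueError(
                        f"activity {i} needs {count} x {rtype!r} but the pool "
                        f"has only {avail} unit(s)"
                    )
            if a.is_initial:
                if a.scheduled_time is None:
                    raise ValueError(f"initial activity {i} lacks scheduled_time")
            elif a.pre is not None:
                p = self.activities[a.pre]
                if p.patient_id != a.patient_id or p.position != a.position - 1:
                    raise ValueError(
                        f"activity {i}: pre must be the same patient's "
                        "immediately preceding activity"
                    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def sample_cohort(
    profiles: Sequence[PathwayProfile],
    n_patients: int,
    arrival_interval: int,
    seed: int | np.random.Generator = 0,
) -> list[PatientVisit]:
    """Draw a cohort: patient ``i`` arrives at ``i * arrival_interval`` and
    follows a pathway sampled by the profile proportions."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if arrival_interval < 1:
        raise ValueError("arrival_interval must be >= 1")
    weights = np.array([p.proportion for p in profiles], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(
            f"profile proportions must sum to 1 (got {weights.sum():.12f})"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    picks = rng.choice([p.path_id for p in profiles], size=n_patients, p=weights)
    return [
        PatientVisit(patient_id=i, path_id=int(picks[i]), scheduled_time=i * arrival_interval)
        for i in range(n_patients)
    ]


def _parse_step(label: str) -> dict[str, int]:
    """Requirement row from a (possibly compound) step label.

    ``"Provider"`` -> one Provider unit; ``"Provider+Provider+Nurse"`` ->
    two Provider units and one Nurse.
    """
    req: dict[str, int] = {}
    for part in label.split("+"):
        req[part] = req.get(part, 0) + 1
    return req


def build_instance(
    cohort: Sequence[PatientVisit],
    profiles: Sequence[PathwayProfile],
    pool: ResourcePool,
    horizon: int = 240,
) -> ProblemInstance:
    """Expand a cohort into the activity-level optimization instance."""
    by_id = {p.path_id: p for p in profiles}
    activities: list[Activity] = []
    for visit in cohort:
        if visit.path_id not in by_id:
            raise ValueError(f"unknown path_id {visit.path_id}")
        prof = by_id[visit.path_id]
        for pos, label in enumerate(prof.activity_sequence):
            req = _parse_step(label)
            for rtype in req:
                if not pool.units_of(rtype):
                    raise ValueError(
                        f"path {prof.path_id} requires unknown resource type "
                        f"{rtype!r}"
                    )
            activities.append(
                Activity(
                    index=len(activities),
                    patient_id=visit.patient_id,
                    position=pos,
                    requirements=req,
                    pre=len(activities) - 1 if pos > 0 else None,
                    scheduled_time=visit.scheduled_time if pos == 0 else None,
                    duration_mean=prof.duration_mean[pos],
                    duration_variance=prof.duration_variance[pos],
                )
            )
    return ProblemInstance(activities=tuple(activities), pool=pool, horizon=horizon)


def sample_scenarios(
    instance: ProblemInstance,
    n_scenarios: int,
    seed: int | np.random.Generator = 0,
) -> list[DurationScenario]:
    """Draw i.i.d. integer duration scenarios from the activity log-normals.

    Continuous draws are rounded to the nearest minute and clamped to at
    least 1; activities and scenarios are independent.
    """
    if n_scenarios < 1:
        raise ValueError("n_scenarios must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cols = []
    for a in instance.activities:
        params = LogNormalParams.from_moments(a.duration_mean, a.duration_variance)
        cols.append(params.sample(rng, n_scenarios))
    raw = np.column_stack(cols)  # (N, |A|)
    d = np.maximum(1, np.floor(raw + 0.5)).astype(np.int64)
    return [DurationScenario(durations=d[n], index=n) for n in range(n_scenarios)]


def mean_value_durations(instance: ProblemInstance) -> DurationScenario:
    """The deterministic mean-value scenario: round(mean), clamped to 1."""
    d = np.array(
        [max(1, int(math.floor(a.duration_mean + 0.5))) for a in instance.activities],
        dtype=np.int64,
    )
    return DurationScenario(durations=d, index=-1, label="mean-value")
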