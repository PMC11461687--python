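"""Care-pathway mining from real-time location system (RTLS) logs.

An RTLS deployment produces two streams of room-level, time-stamped events:
patient room occupancies and resource (staff/equipment) room presences. A
*co-location activity* is a maximal time interval during which a patient
shares a room with a fixed multiset of resource types; the chronological
sequence of such activities within one visit is the patient's *care
pathway*. This module parses the two logs, segments visits into activities,
groups identical type-label sequences into dominant pathway profiles with
occurrence proportions and per-activity duration moments, fits log-normal
duration models by moment matching, and generates synthetic logs with a
known ground truth for testing the whole pipeline.

All times are handled at one-minute granularity: timestamps are floored to
whole minutes before segmentation, and durations are integer minutes.
Intervals are half-open, ``[start, end)``; a zero-length intersection is not
an activity.
"""

from __future__ import annotations

import io
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

PATIENT_COLUMNS = (
    "patient_id",
    "visit_start",
    "visit_end",
    "move_start",
    "move_end",
    "room_name",
    "room_id",
)
RESOURCE_COLUMNS = (
    "resource_id",
    "resource_type",
    "room_name",
    "room_type",
    "start",
    "end",
)
_PATIENT_TIME_COLS = ("visit_start", "visit_end", "move_start", "move_end")
_RESOURCE_TIME_COLS = ("start", "end")


class SchemaError(ValueError):
    """A log file does not conform to the declared column schema."""


class TimestampError(ValueError):
    """A log row carries an unparseable timestamp."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientEvent:
    """One room occupancy of one patient.

    ``move_start``/``move_end`` bound the stay in ``room_id``;
    ``visit_start``/``visit_end`` bound the whole clinic visit.
    """

    patient_id: str
    room_id: str
    room_name: str
    visit_start: pd.Timestamp
    visit_end: pd.Timestamp
    move_start: pd.Timestamp
    move_end: pd.Timestamp


@dataclass(frozen=True)
class ResourceEvent:
    """One room presence of one resource unit (staff member or equipment)."""

    resource_id: str
    resource_type: str
    room_name: str
    room_type: str
    start: pd.Timestamp
    end: pd.Timestamp


@dataclass(frozen=True)
class ActivityObservation:
    """One mined co-location activity within a patient visit.

    ``resource_types`` is the multiset of co-located resource-type labels,
    stored as a sorted tuple. ``start``/``end`` are integer minutes since
    the epoch; ``duration = end - start`` in minutes.
    """

    patient_id: str
    ordinal: int
    resource_types: tuple[str, ...]
    room_id: str
    start: int
    end: int

    @property
    def duration(self) -> int:
        return self.end - self.start

    @property
    def type_label(self) -> str:
        """Compound label, e.g. ``"Provider"`` or ``"Nurse+Provider"``."""
        return "+".join(self.resource_types)


@dataclass(frozen=True)
class PathwayProfile:
    """One dominant pathway: an exact activity-type sequence with its
    occurrence proportion and per-activity duration moments (minutes)."""

    path_id: int
    activity_sequence: tuple[str, ...]
    proportion: float
    duration_mean: tuple[float, ...]
    duration_variance: tuple[float, ...]

    def __post_init__(self) -> None:
        k = len(self.activity_sequence)
        if len(self.duration_mean) != k or len(self.duration_variance) != k:
            raise ValueError(
                f"path {self.path_id}: moment vectors must match sequence "
                f"length {k}"
            )
        if any(m <= 0 for m in self.duration_mean):
            raise ValueError(f"path {self.path_id}: duration means must be > 0")
        if any(v < 0 for v in self.duration_variance):
            raise ValueError(f"path {self.path_id}: variances must be >= 0")
        if not (0.0 <= self.proportion <= 1.0):
            raise ValueError(f"path {self.path_id}: proportion outside [0, 1]")


@dataclass(frozen=True)
class LogNormalParams:
    """Log-normal duration model parameterized by its first two moments.

    The underlying normal parameters follow from moment inversion::

        sigma^2 = ln(1 + variance / mean^2)
        mu      = ln(mean) - sigma^2 / 2
    """

    mean: float
    variance: float
    mu: float
    sigma: float

    @classmethod
    def from_moments(cls, mean: float, variance: float) -> "LogNormalParams":
        if mean <= 0:
            raise ValueError(f"mean must be positive, got {mean}")
        if variance < 0:
            raise ValueError(f"variance must be non-negative, got {variance}")
        if variance == 0:
            return cls(mean=mean, variance=0.0, mu=math.log(mean), sigma=0.0)
        sigma2 = math.log1p(variance / mean**2)
        mu = math.log(mean) - sigma2 / 2.0
        return cls(mean=mean, variance=variance, mu=mu, sigma=math.sqrt(sigma2))

    def moments(self) -> tuple[float, float]:
        """Round-trip: recover (mean, variance) from (mu, sigma)."""
        m = math.exp(self.mu + self.sigma**2 / 2.0)
        v = (math.exp(self.sigma**2) - 1.0) * m**2
        return m, v

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Continuous (pre-rounding) draws in minutes."""
        if self.sigma == 0.0:
            return np.full(size, self.mean)
        return rng.lognormal(self.mu, self.sigma, size)


@dataclass
class CleaningReport:
    """Counts of rows dropped while parsing raw RTLS logs."""

    patient_rows: int = 0
    resource_rows: int = 0
    dropped_inverted: int = 0
    dropped_missing_id: int = 0
    dropped_rows: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _read_log(
    source, columns: Sequence[str], time_cols: Sequence[str]
) -> pd.DataFrame:
    df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    for col in time_cols:
        parsed = pd.to_datetime(df[col], errors="coerce", format="ISO8601")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 2  # 1-based, after the header
            raise TimestampError(
                f"unparseable timestamp in column {col!r} at line {line}: "
                f"{df.loc[df.index[bad][0], col]!r}"
            )
        df[col] = parsed
    return df


def parse_rtls_logs(
    patient_log, resource_log
) -> tuple[list[PatientEvent], list[ResourceEvent], CleaningReport]:
    """Parse the two delimited RTLS logs into validated event lists.

    Rows with inverted intervals (end before start) or missing identifiers
    are dropped and counted in the returned :class:`CleaningReport`.
    Surviving events are sorted by (identifier, start time).
    """
    pdf = _read_log(patient_log, PATIENT_COLUMNS, _PATIENT_TIME_COLS)
    rdf = _read_log(resource_log, RESOURCE_COLUMNS, _RESOURCE_TIME_COLS)
    report = CleaningReport(patient_rows=len(pdf), resource_rows=len(rdf))

    p_missing = pdf["patient_id"].isna() | pdf["room_id"].isna()
    p_inverted = (pdf["move_end"] < pdf["move_start"]) | (
        pdf["visit_end"] < pdf["visit_start"]
    )
    r_missing = rdf["resource_id"].isna() | rdf["resource_type"].isna()
    r_inverted = rdf["end"] < rdf["start"]
    report.dropped_missing_id = int(p_missing.sum() + r_missing.sum())
    report.dropped_inverted = int(
        (p_inverted & ~p_missing).sum() + (r_inverted & ~r_missing).sum()
    )
    report.dropped_rows = [int(i) for i in pdf.index[p_missing | p_inverted]]

    pdf = pdf[~(p_missing | p_inverted)].sort_values(
        ["patient_id", "move_start"], kind="stable"
    )
    rdf = rdf[~(r_missing | r_inverted)].sort_values(
        ["resource_id", "start"], kind="stable"
    )

    patients = [
        PatientEvent(
            patient_id=row.patient_id,
            room_id=row.room_id,
            room_name=row.room_name,
            visit_start=row.visit_start,
            visit_end=row.visit_end,
            move_start=row.move_start,
            move_end=row.move_end,
        )
        for row in pdf.itertuples(index=False)
    ]
    resources = [
        ResourceEvent(
            resource_id=row.resource_id,
            resource_type=row.resource_type,
            room_name=row.room_name,
            room_type=row.room_type,
            start=row.start,
            end=row.end,
        )
        for row in rdf.itertuples(index=False)
    ]
    return patients, resources, report


# ---------------------------------------------------------------------------
# Activity extraction
# ---------------------------------------------------------------------------


def _minutes(ts: pd.Timestamp) -> int:
    """Floor a timestamp to whole minutes since the epoch."""
    return int(pd.Timestamp(ts).value // 60_000_000_000)


def extract_activities(
    patient_events: Iterable[PatientEvent],
    resource_events: Iterable[ResourceEvent],
    min_overlap: int = 1,
) -> list[ActivityObservation]:
    """Segment patient visits into co-location activities.

    Within each patient room occupancy, the time axis is cut at every
    boundary where the set of co-located resources changes; maximal
    segments with a constant non-empty resource-type multiset become
    observations. A room change or a change of the co-located type multiset
    starts a new activity; a swap between two units of the same type does
    not. Segments shorter than ``min_overlap`` minutes are discarded.

    Patients with no co-location at all are flagged via a log warning and
    yield no observations (they are thereby excluded from grouping).
    """
    trees: dict[str, IntervalTree] = {}
    for ev in resource_events:
        lo, hi = _minutes(ev.start), _minutes(ev.end)
        if hi > lo:
            # Data carries the unit id so that two units of the same type
            # present simultaneously both contribute to the multiset.
            trees.setdefault(ev.room_name, IntervalTree()).addi(
                lo, hi, (ev.resource_type, ev.resource_id)
            )

    by_patient: dict[str, list[PatientEvent]] = {}
    for ev in patient_events:
        by_patient.setdefault(ev.patient_id, []).append(ev)

    out: list[ActivityObservation] = []
    for pid, events in by_patient.items():
        events.sort(key=lambda e: (_minutes(e.move_start), _minutes(e.move_end)))
        segments: list[tuple[str, tuple[str, ...], int, int]] = []
        for ev in events:
            lo, hi = _minutes(ev.move_start), _minutes(ev.move_end)
            if hi <= lo:
                continue
            tree = trees.get(ev.room_name)
            hits = sorted(tree.overlap(lo, hi)) if tree is not None else []
            bounds = sorted(
                {lo, hi}
                | {max(lo, h.begin) for h in hits}
                | {min(hi, h.end) for h in hits}
            )
            for a, b in zip(bounds[:-1], bounds[1:]):
                types = tuple(
                    sorted(h.data[0] for h in hits if h.begin <= a and h.end >= b)
                )
                if types:
                    segments.append((ev.room_id, types, a, b))
        # Merge contiguous segments with identical room and type multiset
        # (e.g. across consecutive rows for the same room stay).
        merged: list[list] = []
        for room, types, a, b in segments:
            if merged and merged[-1][0] == room and merged[-1][1] == types and (
                merged[-1][3] == a
            ):
                merged[-1][3] = b
            else:
                merged.append([room, types, a, b])
        kept = [m for m in merged if m[3] - m[2] >= min_overlap]
        if not kept:
            logger.warning("patient %s has no co-location; visit excluded", pid)
            continue
        for ordinal, (room, types, a, b) in enumerate(kept):
            out.append(
                ActivityObservation(
                    patient_id=pid,
                    ordinal=ordinal,
                    resource_types=types,
                    room_id=room,
                    start=a,
                    end=b,
                )
            )
    return out


def observations_to_visits(
    observations: Iterable[ActivityObservation],
) -> dict[str, list[ActivityObservation]]:
    """Group observations into per-patient, ordinal-sorted visit sequences."""
    visits: dict[str, list[ActivityObservation]] = {}
    for obs in observations:
        visits.setdefault(obs.patient_id, []).append(obs)
    for seq in visits.values():
        seq.sort(key=lambda o: o.ordinal)
    return visits


# ---------------------------------------------------------------------------
# Pathway grouping
# ---------------------------------------------------------------------------


def group_pathways(
    visits: Mapping[str, Sequence[ActivityObservation]] | Sequence[Sequence[ActivityObservation]],
    top_k: int = 5,
) -> list[PathwayProfile]:
    """Group visits by exact activity-type-sequence equality.

    The ``top_k`` most frequent sequences are retained and their
    proportions renormalized over the retained set, so they can later be
    used directly as pathway sampling weights. Per-activity duration sample
    means and (population) variances are attached to each profile.
    """
    seqs = visits.values() if isinstance(visits, Mapping) else visits
    groups: dict[tuple[str, ...], list[Sequence[ActivityObservation]]] = {}
    for visit in seqs:
        key = tuple(obs.type_label for obs in visit)
        if key:
            groups.setdefault(key, []).append(visit)
    if not groups:
        return []
    if top_k > len(groups):
        logger.warning(
            "top_k=%d exceeds the %d distinct sequences; returning all",
            top_k,
            len(groups),
        )
        top_k = len(groups)
    ranked = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))[:top_k]
    total = sum(len(v) for _, v in ranked)
    profiles = []
    for path_id, (key, members) in enumerate(ranked):
        durs = np.array(
            [[obs.duration for obs in visit] for visit in members], dtype=float
        )
        profiles.append(
            PathwayProfile(
                path_id=path_id,
                activity_sequence=key,
                proportion=len(members) / total,
                duration_mean=tuple(durs.mean(axis=0)),
                duration_variance=tuple(durs.var(axis=0)),
            )
        )
    return profiles


def fit_lognormal_moments(samples: Sequence[float]) -> LogNormalParams:
    """Fit a log-normal by matching the sample mean and variance.

    Requires at least two strictly positive samples; a zero sample variance
    degenerates to a point mass (``sigma = 0``, ``mu = ln mean``).
    """
    arr = np.asarray(samples, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 samples to fit moments")
    bad = arr[arr <= 0]
    if bad.size:
        raise ValueError(f"all samples must be positive; offending value {bad[0]}")
    return LogNormalParams.from_moments(float(arr.mean()), float(arr.var()))


# ---------------------------------------------------------------------------
# Synthetic log generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixedIntervalArrivals:
    """Deterministic equal-interval visit starts from a fixed origin."""

    interval: int = 10
    origin: str = "2020-01-06T08:00:00"

    def start_minute(self, visit_index: int) -> int:
        return _minutes(pd.Timestamp(self.origin)) + visit_index * self.interval


def generate_synthetic_rtls(
    profiles: Sequence[PathwayProfile],
    n_visits: int,
    arrival_model: FixedIntervalArrivals | None = None,
    seed: int = 0,
    n_rooms: int = 100,
    units_per_type: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit consistent patient and resource logs for a synthetic cohort.

    For each visit a pathway is sampled by proportion and each activity
    duration is drawn from the profile's moment-matched log-normal, rounded
    to at least one whole minute. Consecutive activities of a visit
    alternate between two dedicated rooms so that every activity boundary
    is recoverable, and each activity gets one co-located resource row per
    required unit. Deterministic under ``seed``. Round-tripping the result
    through :func:`parse_rtls_logs` -> :func:`extract_activities` ->
    :func:`group_pathways` recovers the generating sequences.
    """
    if n_visits < 1:
        raise ValueError("n_visits must be >= 1")
    if not profiles:
        raise ValueError("need at least one profile")
    arrival_model = arrival_model or FixedIntervalArrivals()
    rng = np.random.default_rng(seed)
    weights = np.array([p.proportion for p in profiles], dtype=float)
    weights = weights / weights.sum()
    path_choice = rng.choice(len(profiles), size=n_visits, p=weights)

    prows: list[tuple] = []
    rrows: list[tuple] = []
    unit_counter: Counter[str] = Counter()
    for v in range(n_visits):
        prof = profiles[path_choice[v]]
        t = arrival_model.start_minute(v)
        visit_start = t
        acts: list[tuple[int, int, str, int]] = []  # (start, end, label, room)
        for pos, label in enumerate(prof.activity_sequence):
            params = LogNormalParams.from_moments(
                prof.duration_mean[pos], prof.duration_variance[pos]
            )
            dur = max(1, int(round(float(params.sample(rng, 1)[0]))))
            room = (2 * v + pos % 2) % n_rooms
            acts.append((t, t + dur, label, room))
            t += dur
        visit_end = t
        for start, end, label, room in acts:
            room_id = f"R{room:03d}"
            room_name = f"Room {room:03d}"
            prows.append(
                (
                    f"P{v:06d}",
                    visit_start,
                    visit_end,
                    start,
                    end,
                    room_name,
                    room_id,
                )
            )
            for rtype in label.split("+"):
                unit = unit_counter[rtype] % units_per_type
                unit_counter[rtype] += 1
                rrows.append(
                    (
                        f"{rtype}-{unit:02d}",
                        rtype,
                        room_name,
                        "Exam Room",
                        start,
                        end,
                    )
                )

    def _ts(col: pd.Series) -> pd.Series:
        return pd.to_datetime(col.astype("int64") * 60_000_000_000)

    pdf = pd.DataFrame(prows, columns=list(PATIENT_COLUMNS))
    for col in _PATIENT_TIME_COLS:
        pdf[col] = _ts(pdf[col])
    rdf = pd.DataFrame(rrows, columns=list(RESOURCE_COLUMNS))
    for col in _RESOURCE_TIME_COLS:
        rdf[col] = _ts(rdf[col])
    return pdf, rdf


def write_rtls_logs(
    patient_df: pd.DataFrame, resource_df: pd.DataFrame, patient_path, resource_path
) -> None:
    """Write the two logs as comma-separated text with ISO-8601 timestamps."""
    patient_df.to_csv(patient_path, index=False, date_format="%Y-%m-%dT%H:%M:%S")
    resource_df.to_csv(resource_path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def logs_to_text(patient_df: pd.DataFrame, resource_df: pd.DataFrame) -> tuple[str, str]:
    """Render both logs to CSV text (used for determinism checks)."""
    pbuf, rbuf = io.StringIO(), io.StringIO()
    write_rtls_logs(patient_df, resource_df, pbuf, rbuf)
    return pbuf.getvalue(), rbuf.getvalue()


# ---------------------------------------------------------------------------
# Profile round-tripping
# ---------------------------------------------------------------------------


def profiles_to_frame(profiles: Sequence[PathwayProfile]) -> pd.DataFrame:
    """Tabular view: one row per pathway, list-valued columns serialized."""
    return pd.DataFrame(
        {
            "path_id": [p.path_id for p in profiles],
            "activity_sequence": ["|".join(p.activity_sequence) for p in profiles],
            "proportion": [p.proportion for p in profiles],
            "duration_mean": [
                "|".join(f"{m:g}" for m in p.duration_mean) for p in profiles
            ],
            "duration_variance": [
                "|".join(f"{v:g}" for v in p.duration_variance) for p in profiles
            ],
        }
    )


def write_profiles(profiles: Sequence[PathwayProfile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_profiles(path) -> list[PathwayProfile]:
    df = pd.read_csv(path)
    return [
        PathwayProfile(
            path_id=int(row.path_id),
            activity_sequence=tuple(str(row.activity_sequence).split("|")),
            proportion=float(row.proportion),
            duration_mean=tuple(
                float(x) for x in str(row.duration_mean).split("|")
            ),
            duration_variance=tuple(
                float(x) for x in str(row.duration_variance).split("|")
            ),
        )
        for row in df.itertuples(index=False)
    ]
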