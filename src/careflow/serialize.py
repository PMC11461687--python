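"""JSON/CSV round-tripping of instances, scenarios and first-stage plans."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .instance import (
    Activity,
    DurationScenario,
    ProblemInstance,
    ResourcePool,
    ResourceUnit,
)
from .milp import FirstStageSolution


def instance_to_dict(instance: ProblemInstance) -> dict:
    return {
        "horizon": instance.horizon,
        "pool": [
            {"unit_id": u.unit_id, "rtype": u.rtype, "capacity": u.capacity}
            for u in instance.pool.units
        ],
        "activities": [
            {
                "index": a.index,
                "patient_id": a.patient_id,
                "position": a.position,
                "requirements": dict(a.requirements),
                "pre": a.pre,
                "scheduled_time": a.scheduled_time,
                "duration_mean": a.duration_mean,
                "duration_variance": a.duration_variance,
            }
            for a in instance.activities
        ],
    }


def instance_from_dict(data: dict) -> ProblemInstance:
    pool = ResourcePool(
        units=tuple(
            ResourceUnit(u["unit_id"], u["rtype"], u["capacity"])
            for u in data["pool"]
        )
    )
    acts = tuple(
        Activity(
            index=a["index"],
            patient_id=a["patient_id"],
            position=a["position"],
            requirements=a["requirements"],
            pre=a["pre"],
            scheduled_time=a["scheduled_time"],
            duration_mean=a["duration_mean"],
            duration_variance=a["duration_variance"],
        )
        for a in data["activities"]
    )
    return ProblemInstance(activities=acts, pool=pool, horizon=data["horizon"])


def write_instance(instance: ProblemInstance, path: str | Path) -> None:
    Path(path).write_text(json.dumps(instance_to_dict(instance), indent=2) + "\n")


def read_instance(path: str | Path) -> ProblemInstance:
    return instance_from_dict(json.loads(Path(path).read_text()))


def write_scenarios(scenarios: Sequence[DurationScenario], path: str | Path) -> None:
    """One row per scenario, one duration column per activity."""
    df = pd.DataFrame(
        np.vstack([s.durations for s in scenarios]),
        columns=[f"a{i}" for i in range(len(scenarios[0].durations))],
    )
    df.insert(0, "scenario", [s.index for s in scenarios])
    df.to_csv(path, index=False)


def read_scenarios(path: str | Path) -> list[DurationScenario]:
    df = pd.read_csv(path)
    return [
        DurationScenario(
            durations=row[1:].to_numpy(dtype=np.int64), index=int(row.iloc[0])
        )
        for _, row in df.iterrows()
    ]


def first_stage_to_dict(fs: FirstStageSolution) -> dict:
    return {
        "x": [[a, j, v] for (a, j), v in sorted(fs.x.items())],
        "s1": [[a, ap, v] for (a, ap), v in sorted(fs.s1.items())],
        "s2": [[a, ap, v] for (a, ap), v in sorted(fs.s2.items())],
        "q": [[a, ap, j, v] for (a, ap, j), v in sorted(fs.q.items())],
    }


def first_stage_from_dict(data: dict) -> FirstStageSolution:
    return FirstStageSolution(
        x={(a, j): v for a, j, v in data["x"]},
        s1={(a, ap): v for a, ap, v in data["s1"]},
        s2={(a, ap): v for a, ap, v in data["s2"]},
        q={(a, ap, j): v for a, ap, j, v in data["q"]},
    )


def write_first_stage(fs: FirstStageSolution, path: str | Path) -> None:
    Path(path).write_text(json.dumps(first_stage_to_dict(fs)) + "\n")


def read_first_stage(path: str | Path) -> FirstStageSolution:
    return first_stage_from_dict(json.loads(Path(path).read_text()))
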