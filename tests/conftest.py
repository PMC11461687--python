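"""Shared fixtures: tiny hand-built instances and a random-instance factory."""

from __future__ import annotations

import numpy as np
import pytest

import careflow as cf


@pytest.fixture(scope="session")
def clinic_profiles():
    return cf.ORTHO_CLINIC_PROFILES


@pytest.fixture()
def two_patient_provider_instance():
    """2 patients on [Intake, Provider], both scheduled at t=0, two Intake
    units and a single capacity-1 Provider; deterministic d=(2,5). The
    optimum delays one Provider start from 2 to 7, so v = 5."""
    prof = cf.PathwayProfile(0, ("Intake", "Provider"), 1.0, (2.0, 5.0), (0.0, 0.0))
    pool = cf.ResourcePool(
        units=(
            cf.ResourceUnit("Intake-00", "Intake", 1),
            cf.ResourceUnit("Intake-01", "Intake", 1),
            cf.ResourceUnit("Provider-00", "Provider", 1),
        )
    )
    cohort = [cf.PatientVisit(0, 0, 0), cf.PatientVisit(1, 0, 0)]
    inst = cf.build_instance(cohort, [prof], pool, horizon=60)
    return inst, cf.mean_value_durations(inst)


def random_tiny_instance(seed: int):
    """Randomized tiny instance (2-3 patients, chains <= 3, <= 2 units per
    type, capacities in {1, 2}) with one deterministic scenario, small
    enough for the brute-force oracle."""
    rng = np.random.default_rng(seed)
    n_pat = int(rng.integers(2, 4))
    types = ["T0", "T1"]
    units = []
    for t in types:
        for i in range(int(rng.integers(1, 3))):
            units.append(cf.ResourceUnit(f"{t}-{i}", t, int(rng.integers(1, 3))))
    pool = cf.ResourcePool(units=tuple(units))
    profs = []
    for p in range(2):
        length = int(rng.integers(1, 4))
        seq = tuple(rng.choice(types) for _ in range(length))
        means = tuple(float(rng.integers(1, 5)) for _ in range(length))
        profs.append(
            cf.PathwayProfile(p, seq, 0.5, means, tuple(0.0 for _ in seq))
        )
    cohort = [
        cf.PatientVisit(i, int(rng.integers(0, 2)), int(i * rng.integers(1, 6)))
        for i in range(n_pat)
    ]
    inst = cf.build_instance(cohort, profs, pool, horizon=120)
    scenario = cf.sample_scenarios(inst, 1, rng)[0]
    return inst, scenario


def oracle_horizon(inst, scenario) -> int:
    t_max = max((a.scheduled_time or 0) for a in inst.activities)
    return int(t_max + np.asarray(scenario.durations).sum() + 1)
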