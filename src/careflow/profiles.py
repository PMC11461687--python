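"""Reference pathway profiles for an outpatient orthopedics clinic.

These five dominant pathways — with occurrence proportions renormalized over
the dominant set and log-normal duration moments in minutes — describe the
visit structure of a walk-through orthopedics clinic: every visit opens with
Intake and closes with Discharge, with Radiology Technician, Provider and
Orthopedics Technician encounters in between depending on the care needed.
They serve as the default input for cohort generation, synthetic RTLS logs
and the experiment driver.
"""

from __future__ import annotations

from .pathways import PathwayProfile

#: Resource types that act as capacity bottlenecks in the clinic; Intake and
#: Discharge stations are effectively uncapacitated.
BOTTLENECK_TYPES = ("Radiology Tech", "Provider", "Ortho Tech")

ORTHO_CLINIC_PROFILES: tuple[PathwayProfile, ...] = (
    PathwayProfile(
        path_id=0,
        activity_sequence=(
            "Intake",
            "Radiology Tech",
            "Provider",
            "Ortho Tech",
            "Discharge",
        ),
        proportion=0.3803,
        duration_mean=(4.7, 3.48, 4.52, 11.62, 3.43),
        duration_variance=(3.25, 4.85, 13.9, 185.52, 2.63),
    ),
    PathwayProfile(
        path_id=1,
        activity_sequence=("Intake", "Provider", "Ortho Tech", "Discharge"),
        proportion=0.2455,
        duration_mean=(4.93, 4.99, 12.47, 3.69),
        duration_variance=(4.0, 20.11, 206.96, 2.92),
    ),
    PathwayProfile(
        path_id=2,
        activity_sequence=("Intake", "Ortho Tech", "Discharge"),
        proportion=0.1393,
        duration_mean=(4.75, 11.82, 3.44),
        duration_variance=(4.35, 232.7, 3.36),
    ),
    PathwayProfile(
        path_id=3,
        activity_sequence=("Intake", "Radiology Tech", "Ortho Tech", "Discharge"),
        proportion=0.1378,
        duration_mean=(4.91, 3.58, 11.25, 3.49),
        duration_variance=(3.75, 5.79, 224.31, 3.31),
    ),
    PathwayProfile(
        path_id=4,
        activity_sequence=("Intake", "Radiology Tech", "Provider", "Discharge"),
        proportion=0.0971,
        duration_mean=(5.06, 3.52, 6.15, 3.62),
        duration_variance=(3.98, 4.95, 30.61, 4.06),
    ),
)
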