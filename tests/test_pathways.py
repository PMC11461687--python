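"""Mining pipeline: parsing, segmentation, grouping, log-normal fitting."""

from __future__ import annotations

import io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import careflow as cf
from careflow.pathways import (
    CleaningReport,
    SchemaError,
    TimestampError,
    logs_to_text,
)


def _ts(minute: int) -> pd.Timestamp:
    return pd.Timestamp("2020-01-06T08:00:00") + pd.Timedelta(minutes=minute)


def _patient_event(pid, room, lo, hi, vlo=None, vhi=None):
    return cf.PatientEvent(
        patient_id=pid,
        room_id=room,
        room_name=f"Room {room}",
        visit_start=_ts(vlo if vlo is not None else lo),
        visit_end=_ts(vhi if vhi is not None else hi),
        move_start=_ts(lo),
        move_end=_ts(hi),
    )


def _resource_event(rid, rtype, room, lo, hi):
    return cf.ResourceEvent(
        resource_id=rid,
        resource_type=rtype,
        room_name=f"Room {room}",
        room_type="Exam Room",
        start=_ts(lo),
        end=_ts(hi),
    )


# ---------------------------------------------------------------------------
# Log-normal moment fitting
# ---------------------------------------------------------------------------


class TestLogNormalMoments:
    def test_constant_samples_degenerate(self):
        params = cf.fit_lognormal_moments([5, 5, 5])
        assert params.mean == 5
        assert params.variance == 0
        assert params.sigma == 0
        assert params.mu == pytest.approx(math.log(5))

    def test_closed_form_inversion(self):
        # first activity of the dominant five-step pathway: mean 4.7 min,
        # variance 3.25 min^2
        params = cf.LogNormalParams.from_moments(4.7, 3.25)
        sigma2 = math.log(1 + 3.25 / 4.7**2)
        assert params.sigma**2 == pytest.approx(sigma2, rel=1e-12)
        assert params.mu == pytest.approx(math.log(4.7) - sigma2 / 2, rel=1e-12)

    @given(
        mean=st.floats(0.1, 500.0),
        variance=st.floats(0.0, 1e4),
    )
    @settings(max_examples=200, deadline=None)
    def test_moment_round_trip(self, mean, variance):
        params = cf.LogNormalParams.from_moments(mean, variance)
        m, v = params.moments()
        assert m == pytest.approx(mean, rel=1e-9)
        assert v == pytest.approx(variance, rel=1e-9, abs=1e-9)

    def test_monte_carlo_parameter_recovery(self):
        mu_star, sigma_star = 1.3, 0.7
        rng = np.random.default_rng(2024)
        draws = rng.lognormal(mu_star, sigma_star, 100_000)
        params = cf.fit_lognormal_moments(draws)
        assert params.mu == pytest.approx(mu_star, rel=0.02)
        assert params.sigma == pytest.approx(sigma_star, rel=0.02)

    def test_rejects_nonpositive_samples(self):
        with pytest.raises(ValueError, match="-2"):
            cf.fit_lognormal_moments([3.0, -2.0, 5.0])
        with pytest.raises(ValueError, match="at least 2"):
            cf.fit_lognormal_moments([3.0])


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


class TestParsing:
    def test_empty_file_header_only(self):
        pbuf = io.StringIO(",".join(cf.pathways.PATIENT_COLUMNS) + "\n")
        rbuf = io.StringIO(",".join(cf.pathways.RESOURCE_COLUMNS) + "\n")
        patients, resources, report = cf.parse_rtls_logs(pbuf, rbuf)
        assert patients == [] and resources == []
        assert report.dropped_inverted == 0 and report.dropped_missing_id == 0

    def test_missing_column_named(self):
        pbuf = io.StringIO("patient_id,visit_start\nP0,2020-01-06T08:00:00\n")
        rbuf = io.StringIO(",".join(cf.pathways.RESOURCE_COLUMNS) + "\n")
        with pytest.raises(SchemaError, match="room_id"):
            cf.parse_rtls_logs(pbuf, rbuf)

    def test_bad_timestamp_reports_line(self):
        rows = [
            ",".join(cf.pathways.PATIENT_COLUMNS),
            "P0,2020-01-06T08:00:00,2020-01-06T09:00:00,2020-01-06T08:00:00,2020-01-06T08:10:00,Room 0,R0",
            "P1,not-a-time,2020-01-06T09:00:00,2020-01-06T08:00:00,2020-01-06T08:10:00,Room 0,R0",
        ]
        rbuf = io.StringIO(",".join(cf.pathways.RESOURCE_COLUMNS) + "\n")
        with pytest.raises(TimestampError, match="line 3"):
            cf.parse_rtls_logs(io.StringIO("\n".join(rows)), rbuf)

    def test_inverted_intervals_dropped_and_counted(self):
        rows = [
            ",".join(cf.pathways.PATIENT_COLUMNS),
            "P0,2020-01-06T08:00:00,2020-01-06T09:00:00,2020-01-06T08:00:00,2020-01-06T08:10:00,Room 0,R0",
            "P1,2020-01-06T08:00:00,2020-01-06T09:00:00,2020-01-06T08:30:00,2020-01-06T08:10:00,Room 0,R0",
        ]
        rbuf = io.StringIO(",".join(cf.pathways.RESOURCE_COLUMNS) + "\n")
        patients, _, report = cf.parse_rtls_logs(io.StringIO("\n".join(rows)), rbuf)
        assert len(patients) == 1
        assert report.dropped_inverted == 1

    def test_generator_round_trips_losslessly(self, clinic_profiles):
        pdf, rdf = cf.generate_synthetic_rtls(clinic_profiles, 50, seed=3)
        ptxt, rtxt = logs_to_text(pdf, rdf)
        patients, resources, report = cf.parse_rtls_logs(
            io.StringIO(ptxt), io.StringIO(rtxt)
        )
        assert len(patients) == len(pdf)
        assert len(resources) == len(rdf)
        assert report.dropped_inverted == 0
        # field-by-field equality against the in-memory records
        first = patients[0]
        row = pdf.sort_values(["patient_id", "move_start"]).iloc[0]
        assert first.patient_id == row.patient_id
        assert first.room_id == row.room_id
        assert first.move_start == row.move_start
        assert first.move_end == row.move_end


# ---------------------------------------------------------------------------
# Activity extraction
# ---------------------------------------------------------------------------


class TestExtraction:
    def test_single_full_overlap(self):
        obs = cf.extract_activities(
            [_patient_event("P0", "R1", 0, 10)],
            [_resource_event("Provider-0", "Provider", "R1", 0, 10)],
        )
        assert len(obs) == 1
        assert obs[0].resource_types == ("Provider",)
        assert obs[0].duration == 10

    def test_resource_change_splits_activity(self):
        obs = cf.extract_activities(
            [_patient_event("P0", "R1", 0, 10)],
            [
                _resource_event("Provider-0", "Provider", "R1", 0, 4),
                _resource_event("Ortho Tech-0", "Ortho Tech", "R1", 4, 10),
            ],
        )
        assert [(o.type_label, o.duration) for o in obs] == [
            ("Provider", 4),
            ("Ortho Tech", 6),
        ]

    def test_room_change_splits_even_with_same_staff(self):
        obs = cf.extract_activities(
            [
                _patient_event("P0", "R1", 0, 5, vhi=12),
                _patient_event("P0", "R2", 5, 12, vlo=0),
            ],
            [
                _resource_event("Provider-0", "Provider", "R1", 0, 5),
                _resource_event("Provider-0", "Provider", "R2", 5, 12),
            ],
        )
        assert len(obs) == 2
        assert [o.room_id for o in obs] == ["R1", "R2"]
        assert [o.ordinal for o in obs] == [0, 1]

    def test_unit_swap_same_type_does_not_split(self):
        obs = cf.extract_activities(
            [_patient_event("P0", "R1", 0, 10)],
            [
                _resource_event("Provider-0", "Provider", "R1", 0, 6),
                _resource_event("Provider-1", "Provider", "R1", 6, 10),
            ],
        )
        assert len(obs) == 1
        assert obs[0].duration == 10

    def test_two_units_same_type_counted_as_multiset(self):
        obs = cf.extract_activities(
            [_patient_event("P0", "R1", 0, 10)],
            [
                _resource_event("Provider-0", "Provider", "R1", 0, 10),
                _resource_event("Provider-1", "Provider", "R1", 0, 10),
            ],
        )
        assert obs[0].resource_types == ("Provider", "Provider")

    def test_patient_without_colocation_excluded(self, caplog):
        obs = cf.extract_activities([_patient_event("P9", "R1", 0, 10)], [])
        assert obs == []

    def test_segmentation_covers_colocated_time_without_overlap(self):
        obs = cf.extract_activities(
            [_patient_event("P0", "R1", 0, 20)],
            [
                _resource_event("A-0", "A", "R1", 2, 9),
                _resource_event("B-0", "B", "R1", 5, 14),
            ],
        )
        spans = [(o.start % 1440, o.end % 1440) for o in obs]
        total = sum(o.duration for o in obs)
        # co-located minutes are [2, 14): 12 minutes, three segments
        assert total == 12
        assert [o.type_label for o in obs] == ["A", "A+B", "B"]
        for (a, b), (c, d) in zip(spans[:-1], spans[1:]):
            assert b <= c


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------


def _fake_visit(pid, labels, durations):
    return [
        cf.ActivityObservation(
            patient_id=pid,
            ordinal=i,
            resource_types=tuple(lbl.split("+")),
            room_id="R0",
            start=0,
            end=int(d),
        )
        for i, (lbl, d) in enumerate(zip(labels, durations))
    ]


class TestGrouping:
    def test_identical_visits_single_profile(self):
        visits = {f"P{i}": _fake_visit(f"P{i}", ["A", "B"], [3, 4]) for i in range(3)}
        profiles = cf.group_pathways(visits, top_k=5)
        assert len(profiles) == 1
        assert profiles[0].proportion == 1.0
        assert profiles[0].activity_sequence == ("A", "B")
        assert profiles[0].duration_mean == (3.0, 4.0)

    def test_hand_counted_proportions(self):
        visits = {}
        specs = [(["A"], 5), (["A", "B"], 3), (["B"], 2)]
        n = 0
        for labels, count in specs:
            for _ in range(count):
                visits[f"P{n}"] = _fake_visit(f"P{n}", labels, [2] * len(labels))
                n += 1
        profiles = cf.group_pathways(visits, top_k=3)
        assert [p.proportion for p in profiles] == [0.5, 0.3, 0.2]

    def test_top_k_restriction_renormalizes(self):
        visits = {}
        specs = [(["A"], 6), (["B"], 3), (["C"], 1)]
        n = 0
        for labels, count in specs:
            for _ in range(count):
                visits[f"P{n}"] = _fake_visit(f"P{n}", labels, [2])
                n += 1
        profiles = cf.group_pathways(visits, top_k=2)
        assert len(profiles) == 2
        assert sum(p.proportion for p in profiles) == pytest.approx(1.0)
        assert profiles[0].proportion == pytest.approx(6 / 9)

    def test_top_k_above_distinct_returns_all(self, caplog):
        visits = {"P0": _fake_visit("P0", ["A"], [1])}
        profiles = cf.group_pathways(visits, top_k=10)
        assert len(profiles) == 1


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------


class TestGenerator:
    def test_single_visit_single_activity(self):
        prof = cf.PathwayProfile(0, ("Provider",), 1.0, (5.0,), (0.0,))
        pdf, rdf = cf.generate_synthetic_rtls([prof], 1, seed=0)
        assert len(pdf) == 1 and len(rdf) == 1
        assert rdf.iloc[0].resource_type == "Provider"
        assert pdf.iloc[0].move_start == rdf.iloc[0].start
        assert pdf.iloc[0].move_end == rdf.iloc[0].end

    def test_same_seed_byte_identical(self, clinic_profiles):
        a = logs_to_text(*cf.generate_synthetic_rtls(clinic_profiles, 200, seed=17))
        b = logs_to_text(*cf.generate_synthetic_rtls(clinic_profiles, 200, seed=17))
        assert a == b

    def test_round_trip_recovers_generating_sequences(self, clinic_profiles):
        pdf, rdf = cf.generate_synthetic_rtls(clinic_profiles, 3000, seed=11)
        ptxt, rtxt = logs_to_text(pdf, rdf)
        patients, resources, _ = cf.parse_rtls_logs(
            io.StringIO(ptxt), io.StringIO(rtxt)
        )
        visits = cf.observations_to_visits(
            cf.extract_activities(patients, resources)
        )
        mined = cf.group_pathways(visits, top_k=5)
        mined_seqs = {p.activity_sequence for p in mined}
        assert mined_seqs == {p.activity_sequence for p in clinic_profiles}
        # proportions within 3 binomial standard errors of the weights
        n = len(visits)
        by_seq = {p.activity_sequence: p.proportion for p in mined}
        for prof in clinic_profiles:
            se = math.sqrt(prof.proportion * (1 - prof.proportion) / n)
            assert abs(by_seq[prof.activity_sequence] - prof.proportion) < 3 * se

    def test_profile_file_round_trip(self, clinic_profiles, tmp_path):
        path = tmp_path / "profiles.csv"
        cf.write_profiles(clinic_profiles, path)
        back = cf.read_profiles(path)
        assert [p.activity_sequence for p in back] == [
            p.activity_sequence for p in clinic_profiles
        ]
        assert back[0].duration_mean == clinic_profiles[0].duration_mean
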