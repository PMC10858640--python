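"""Synthetic cohort, trajectory and telemetry generators."""

import numpy as np
import pandas as pd
import pytest

import hfscore as h
from hfscore.engine import COMPONENTS
from hfscore.synthetic import (
    CASCADE_COUNTS,
    CASCADE_TOTAL,
    _floored_normal_location,
    events_to_frame,
    patients_to_frame,
)


class TestMakeCohort:
    def test_empty_event_group(self):
        cfg = h.CohortConfig(n_event_patients=0, n_control_patients=10, seed=1)
        patients, events = h.make_cohort(cfg)
        assert len(patients) == 10
        assert events == []

    def test_exact_counts_with_fixed_total(self, small_cohort):
        cfg, patients, events = small_cohort
        assert len(patients) == cfg.n_event_patients + cfg.n_control_patients
        assert len(events) == cfg.total_events
        groups = pd.Series([p.group for p in patients]).value_counts()
        assert groups["event"] == cfg.n_event_patients
        assert groups["control"] == cfg.n_control_patients
        event_pids = {p.patient_id for p in patients if p.group == "event"}
        assert all(e.patient_id in event_pids for e in events)

    def test_determinism(self, small_cohort):
        cfg, patients, events = small_cohort
        patients2, events2 = h.make_cohort(cfg)
        assert patients_to_frame(patients).equals(patients_to_frame(patients2))
        assert events_to_frame(events).equals(events_to_frame(events2))

    def test_patient_subset_independent_of_cohort_size(self):
        small = h.CohortConfig(n_event_patients=5, n_control_patients=0,
                               total_events=7, seed=9)
        big = h.CohortConfig(n_event_patients=5, n_control_patients=50,
                             total_events=7, seed=9)
        p_small, _ = h.make_cohort(small)
        p_big, _ = h.make_cohort(big)
        assert patients_to_frame(p_small).equals(
            patients_to_frame(p_big[:5])
        )

    def test_events_respect_run_in_and_follow_up(self, small_cohort):
        cfg, patients, events = small_cohort
        fu = {p.patient_id: p.follow_up_end for p in patients}
        for e in events:
            assert cfg.min_event_day <= e.admission_day <= fu[e.patient_id]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            h.CohortConfig(n_event_patients=-1, n_control_patients=1)
        with pytest.raises(ValueError):
            h.CohortConfig(1, 1, transmission_probability=1.5)
        with pytest.raises(ValueError):
            h.CohortConfig(1, 1, events_per_patient_probs=(0.5, 0.2, 0.2))
        with pytest.raises(ValueError):
            h.make_cohort(
                h.CohortConfig(2, 0, total_events=100)
            )


class TestFlooredNormal:
    @pytest.mark.parametrize("m,s", [(1.3, 8.0), (0.5, 13.4), (13.7, 6.0), (42.0, 2.0)])
    def test_floored_mean_matches_target(self, m, s):
        mu = _floored_normal_location(np.array([m]), s)[0]
        rng = np.random.default_rng(0)
        draws = np.maximum(rng.normal(mu, s, 400_000), 0.0)
        assert draws.mean() == pytest.approx(m, abs=4 * s / np.sqrt(400_000))

    def test_zero_sd_is_identity(self):
        m = np.array([0.0, 1.5, 42.0])
        assert np.allclose(_floored_normal_location(m, 0.0), m)


class TestComponentScoreSimulation:
    def test_noise_free_flat_controls(self):
        traj = h.TrajectorySpec.noise_free()
        flat = h.TrajectorySpec(
            control_end=dict(traj.control_start),
            patient_sd=traj.patient_sd,
            anchor_sd=traj.anchor_sd,
            residual_sd=traj.residual_sd,
        )
        cfg = h.CohortConfig(0, 3, seed=2)
        patients, events = h.make_cohort(cfg)
        scores = h.simulate_component_scores(patients, events, flat, seed=3)
        for comp in COMPONENTS:
            assert np.allclose(scores[comp], flat.control_start[comp])

    def test_noise_free_event_week0_composite(self):
        """With zero noise the admission-week composite averages the
        configured Week 0 sum (51.6 with defaults)."""
        traj = h.TrajectorySpec.noise_free()
        cfg = h.CohortConfig(3, 0, total_events=3, seed=4)
        patients, events = h.make_cohort(cfg)
        scores = h.simulate_component_scores(patients, events, traj, seed=5)
        for ev in events:
            win = scores[
                (scores["patient_id"] == ev.patient_id)
                & (scores["day"] > ev.admission_day - 7)
                & (scores["day"] <= ev.admission_day)
            ]
            assert win["score"].mean() == pytest.approx(51.6, abs=1e-9)

    def test_noise_free_week_minus12_composite(self):
        traj = h.TrajectorySpec.noise_free()
        cfg = h.CohortConfig(2, 0, total_events=2, seed=6)
        patients, events = h.make_cohort(cfg)
        scores = h.simulate_component_scores(patients, events, traj, seed=7)
        ev = events[0]
        win = scores[
            (scores["patient_id"] == ev.patient_id)
            & (scores["day"] >= ev.admission_day - 90)
            & (scores["day"] <= ev.admission_day - 84)
        ]
        assert win["score"].mean() == pytest.approx(42.3, abs=1e-9)

    def test_non_negativity(self, small_cohort):
        cfg, patients, events = small_cohort
        scores = h.simulate_component_scores(patients, events, seed=8)
        assert (scores[list(COMPONENTS)].to_numpy() >= 0).all()
        assert (scores["score"].to_numpy() >= 0).all()

    def test_weekly_mean_converges_to_trajectory(self):
        """Monte-Carlo convergence of the Week -12 event-group weekly
        composite mean to the configured 42.3 within 3 standard errors."""
        n = 400
        cfg = h.CohortConfig(n, 0, total_events=n, seed=10,
                             follow_up_days=(300, 400))
        patients, events = h.make_cohort(cfg)
        scores = h.simulate_component_scores(patients, events, seed=11)
        anchors = h.select_anchors(patients, events, scores)
        weekly = h.build_weekly_observations(anchors, scores)
        wk12 = weekly[weekly["week"] == -12]["mean_score"]
        se = wk12.std(ddof=1) / np.sqrt(len(wk12))
        assert abs(wk12.mean() - 42.3) < 3 * se

    def test_determinism(self, small_cohort):
        cfg, patients, events = small_cohort
        a = h.simulate_component_scores(patients, events, seed=12,
                                        transmission_probability=0.8)
        b = h.simulate_component_scores(patients, events, seed=12,
                                        transmission_probability=0.8)
        assert a.equals(b)


class TestTelemetrySimulation:
    def test_full_transmission_flags(self):
        cfg = h.CohortConfig(0, 4, transmission_probability=1.0, seed=13)
        patients, events = h.make_cohort(cfg)
        tele = h.simulate_telemetry(patients, events, cfg, seed=14)
        assert tele["transmitted"].all()

    def test_zero_drift_means_no_trend_signal(self):
        """Without pre-event drift the monotone components are ~0 in
        expectation even for event patients."""
        cfg = h.CohortConfig(12, 0, total_events=12, seed=15,
                             transmission_probability=1.0,
                             follow_up_days=(300, 400))
        patients, events = h.make_cohort(cfg)
        spec = h.TelemetrySpec(hr24_drift=0.0, hrv_drift=0.0, ti_drift=0.0,
                               activity_drift=0.0, pvc_drift=0.0,
                               night_hr_sd_at_event=3.4,
                               ahre_level_start=4.5, ahre_level_at_event=4.5)
        tele = h.simulate_telemetry(patients, events, cfg, seed=16, spec=spec)
        vals = []
        for ev in events:
            sub = tele[tele["patient_id"] == ev.patient_id]
            w = sub[(sub["day"] > ev.admission_day - 84)
                    & (sub["day"] <= ev.admission_day)]
            cs = h.compute_components(w.reset_index(drop=True))
            vals.append([cs.hr24, cs.hrv, cs.ti, cs.activity, cs.pvc])
        means = np.mean(vals, axis=0)
        # clipping at zero leaves a small positive residue; weights are 10-20
        assert (means < 1.5).all()

    def test_transmission_rate_binomial(self):
        cfg = h.CohortConfig(0, 40, transmission_probability=0.5, seed=17,
                             follow_up_days=(90, 90))
        patients, events = h.make_cohort(cfg)
        tele = h.simulate_telemetry(patients, events, cfg, seed=18)
        rate = tele["transmitted"].mean()
        n = len(tele)
        se = np.sqrt(0.25 / n)
        assert abs(rate - 0.5) < 3 * se

    def test_missing_days_carry_no_measurements(self):
        cfg = h.CohortConfig(0, 5, transmission_probability=0.6, seed=19)
        patients, events = h.make_cohort(cfg)
        tele = h.simulate_telemetry(patients, events, cfg, seed=20)
        gaps = tele[~tele["transmitted"]]
        assert gaps[["hr24", "hrv", "impedance"]].isna().all().all()

    def test_hrv_absent_on_ahre_dominated_days(self):
        cfg = h.CohortConfig(10, 0, total_events=10, seed=21,
                             transmission_probability=1.0)
        patients, events = h.make_cohort(cfg)
        tele = h.simulate_telemetry(patients, events, cfg, seed=22)
        high = tele[tele["ahre_pct"] > 20.0]
        assert high["hrv"].isna().all()


class TestFixtures:
    def test_filter_fixture_partition(self):
        fx = h.make_filter_fixture()
        assert len(fx) == CASCADE_TOTAL
        assert sum(CASCADE_COUNTS.values()) + 2050 == CASCADE_TOTAL

    def test_trial_fixture_totals(self):
        patients, events = h.make_trial_fixture()
        assert len(patients) == 2050
        assert len(events) == 369
        assert len({e.patient_id for e in events}) == 259
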