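import numpy as np
import pandas as pd
import pytest

import basalq as bq
from basalq.synthetic_cohort import (
    RawPatientState,
    SimParams,
    cohort_summary,
    generate_cohort,
    optimal_action,
    simulate_transition,
    true_dose_need,
)


class TestTrueDoseNeed:
    def test_lowest_state_needs_base_dose(self):
        assert true_dose_need(bq.StateVector(1, 1, 1, 1)) == 6.0

    def test_high_need_state(self):
        # 6 + 8*2 + 1.5*16 + 5*1 = 51 units, landing in the top interval
        s = bq.StateVector(3, 17, 2, 1)
        assert true_dose_need(s) == 51.0
        assert optimal_action(s) == 6

    def test_monotone_in_every_component(self):
        for s in bq.enumerate_states():
            base = true_dose_need(s)
            a, b, c, d = s.as_tuple()
            for bumped in (
                (min(a + 1, 3), b, c, d),
                (a, min(b + 1, 17), c, d),
                (a, b, min(c + 1, 2), d),
                (a, b, c, min(d + 1, 3)),
            ):
                assert true_dose_need(bq.StateVector(*bumped)) >= base

    def test_clamped_to_dose_support(self):
        for s in bq.enumerate_states():
            assert 6.0 <= true_dose_need(s) <= 100.0


class TestSimulateTransition:
    def test_correct_dose_improves_uncontrolled_patient(self, rng):
        p = SimParams(hba1c_noise_sd=0.0, bmi_walk_sd=0.0)
        raw = RawPatientState(hba1c=8.5, bmi=25.0, activity=1, alcohol=1)
        need = true_dose_need(bq.encode_state(raw.observe()), p)
        nxt, _ = simulate_transition(raw, need, p, rng)
        assert nxt.hba1c < 8.5

    def test_misdosing_never_improves(self, rng):
        p = SimParams(hba1c_noise_sd=0.0, bmi_walk_sd=0.0)
        raw = RawPatientState(hba1c=7.5, bmi=25.0, activity=1, alcohol=1)
        need = true_dose_need(bq.encode_state(raw.observe()), p)
        bad_dose = min(need * (1 + 2.5 * p.need_tolerance), 100.0)
        nxt, _ = simulate_transition(raw, bad_dose, p, rng)
        assert nxt.hba1c >= 7.5

    def test_same_rng_state_is_deterministic(self):
        p = SimParams()
        raw = RawPatientState(hba1c=9.0, bmi=28.0, activity=2, alcohol=1)
        n1, s1 = simulate_transition(raw, 30, p, np.random.default_rng(5))
        n2, s2 = simulate_transition(raw, 30, p, np.random.default_rng(5))
        assert n1 == n2 and s1 == s2

    def test_out_of_support_dose_rejected(self, rng):
        raw = RawPatientState(hba1c=9.0, bmi=28.0, activity=2, alcohol=1)
        with pytest.raises(bq.OutOfSupportError):
            simulate_transition(raw, 4.0, SimParams(), rng)


class TestGenerateCohort:
    def test_default_cohort_shape(self):
        visits = generate_cohort(SimParams(seed=0))
        assert visits["patient_id"].nunique() == 87
        assert (visits.groupby("patient_id").size() == 40).all()
        assert len(visits) == 87 * 40

    def test_doses_within_support(self, small_cohort):
        assert small_cohort["lantus_dose"].between(6, 100).all()

    def test_bit_reproducible(self):
        p = SimParams(n_patients=6, visits_per_patient=10, seed=13)
        assert generate_cohort(p).equals(generate_cohort(p))

    def test_state_space_coverage(self):
        """Default conditions must span HbA1c levels and most BMI bins."""
        from basalq.state_space import encode_visits

        enc = encode_visits(generate_cohort(SimParams(seed=0)))
        assert enc["hba1c_level"].nunique() == 3
        assert enc["bmi_level"].nunique() >= 10

    def test_summary_mentions_counts(self, small_cohort):
        text = cohort_summary(small_cohort)
        assert "patients: 10" in text and "visits:   120" in text


class TestCohortToTransitions:
    def test_three_visits_give_two_transitions(self, clinic_visits):
        trans = bq.cohort_to_transitions(clinic_visits)
        assert len(trans) == 2
        assert [t.s.as_tuple() for t in trans] == [(2, 4, 1, 1), (3, 7, 1, 1)]
        assert trans[0].s_next.as_tuple() == (3, 7, 1, 1)
        assert trans[1].s_next.as_tuple() == (2, 5, 1, 1)
        assert [t.a for t in trans] == [3, 3]
        assert [t.terminal for t in trans] == [False, True]
        # level 2 -> 3 is a deterioration into the uncontrolled band
        assert trans[0].r == -2.0
        assert trans[1].r == 1.0

    def test_empty_frame_gives_no_transitions(self, clinic_visits):
        assert bq.cohort_to_transitions(clinic_visits.iloc[:0]) == []

    def test_single_visit_trajectory_skipped_with_warning(self, clinic_visits, caplog):
        single = clinic_visits.iloc[:1]
        with caplog.at_level("WARNING"):
            assert bq.cohort_to_transitions(single) == []
        assert any("single visit" in r.message for r in caplog.records)


def test_cohort_simulator_protocol():
    sim = bq.CohortSimulator(SimParams(n_patients=2, visits_per_patient=3, seed=1))
    s = sim.reset()
    assert isinstance(s, bq.StateVector)
    for step in range(3):
        s, r, terminal = sim.step(3)
        assert isinstance(s, bq.StateVector) and np.isfinite(r)
    assert terminal


def test_sim_params_validation():
    for kwargs in (
        dict(n_patients=0), dict(need_tolerance=0.0), dict(need_tolerance=1.0),
        dict(hba1c_noise_sd=-0.1), dict(bmi_slope=-1.0),
    ):
        with pytest.raises(ValueError):
            SimParams(**kwargs)
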