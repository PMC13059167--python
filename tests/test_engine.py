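"""State-transition engine: matrix construction, conservation, tunnel
behaviour, case-fatality identities, and microsimulation agreement with
the deterministic cohort solution."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from htncea import (
    HealthState,
    ModelSettings,
    TransitionParameters,
    build_transition_matrix,
    risk_to_cycle_prob,
    run_cohort,
    run_cohort_from_patients,
    run_microsim,
    summarize_events,
)
from htncea.engine import ALIVE_STATES, trajectory_to_long
from htncea.params import DomainError


class TestTransitionMatrix:
    def test_rows_are_stochastic(self, tparams):
        m = build_transition_matrix(0.01, tparams)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)

    @given(
        p_event=st.floats(0, 1),
        p_bg=st.floats(0, 0.1),
        p_mi=st.floats(0.1, 0.9),
    )
    def test_rows_stochastic_for_any_parameters(self, p_event, p_bg, p_mi):
        params = TransitionParameters(p_background_death=p_bg, p_mi_split=p_mi)
        m = build_transition_matrix(p_event, params)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_acute_mi_row_matches_case_fatality(self, tparams):
        m = build_transition_matrix(0.01, tparams)
        assert m[HealthState.ACUTE_MI, HealthState.DEAD_CVD_MI] == 0.65
        assert m[HealthState.ACUTE_MI, HealthState.CHRONIC_IHD] == pytest.approx(0.35)

    def test_no_event_limit(self, tparams):
        m = build_transition_matrix(0.0, tparams)
        row = m[HealthState.NO_CVD]
        assert row[HealthState.DEAD_OTHER] == tparams.p_background_death
        assert row[HealthState.NO_CVD] == pytest.approx(1 - tparams.p_background_death)
        assert row[HealthState.ACUTE_MI] == row[HealthState.ACUTE_STROKE] == 0.0

    def test_dead_rows_absorbing(self, tparams):
        m = build_transition_matrix(0.3, tparams)
        for s in (HealthState.DEAD_CVD_MI, HealthState.DEAD_CVD_STROKE, HealthState.DEAD_OTHER):
            assert m[s, s] == 1.0

    def test_event_probability_domain(self, tparams):
        with pytest.raises(DomainError):
            build_transition_matrix(1.2, tparams)


class TestCohortPropagation:
    def test_conservation_every_cycle(self, tparams, settings):
        traj = run_cohort(100_000, 0.001, tparams, settings)
        totals = traj.occupancy.sum(axis=(0, 2))
        assert np.allclose(totals, 100_000, atol=1e-9)
        assert traj.final_occupancy.sum() == pytest.approx(100_000, abs=1e-9)

    def test_no_event_survival_closed_form(self, tparams, settings):
        traj = run_cohort(100_000, 0.0, tparams, settings)
        expected = 100_000 * (1 - 0.0018) ** 120
        assert traj.occupancy[0, -1, HealthState.NO_CVD] == pytest.approx(
            expected, abs=1e-9 * expected
        )
        assert traj.incident_mi == 0.0

    def test_zero_horizon_is_identity(self, tparams):
        traj = run_cohort(500, 0.01, tparams, ModelSettings(horizon_cycles=0))
        assert traj.occupancy.shape[1] == 1
        assert traj.occupancy[0, 0, HealthState.NO_CVD] == 500

    def test_case_fatality_identities_exact(self, tparams, settings):
        traj = run_cohort(100_000, risk_to_cycle_prob(0.08), tparams, settings)
        d = traj.deaths_by_cause()
        assert d["acute_mi"] / traj.incident_mi == pytest.approx(0.65, abs=1e-12)
        assert d["acute_stroke"] / traj.incident_stroke == pytest.approx(0.38, abs=1e-12)

    def test_tunnel_occupancy_equals_incidence(self, tparams, settings):
        traj = run_cohort(100_000, 0.002, tparams, settings)
        # new acute occupants at index t+1 are exactly the cycle-t events
        assert np.allclose(
            traj.occupancy[0, 1:, HealthState.ACUTE_MI], traj.incident[0, :, 0]
        )
        assert np.allclose(
            traj.occupancy[0, 1:, HealthState.ACUTE_STROKE], traj.incident[0, :, 1]
        )

    def test_matrix_propagation_matches_engine(self, tparams, settings):
        # independent oracle: repeated left-multiplication by the
        # explicit transition matrix (ignoring the terminal resolution)
        p = 0.003
        m = build_transition_matrix(p, tparams)
        v = np.zeros(8)
        v[HealthState.NO_CVD] = 1000.0
        traj = run_cohort(1000.0, p, tparams, settings)
        for t in range(settings.horizon_cycles + 1):
            assert np.allclose(traj.occupancy[0, t], v, atol=1e-9)
            v = v @ m

    def test_first_events_only(self, tparams, settings):
        # cumulative events can never exceed the people ever leaving NoCVD
        traj = run_cohort(10_000, 0.01, tparams, settings)
        left_no_cvd = 10_000 - traj.occupancy[0, -1, HealthState.NO_CVD]
        assert traj.incident_mi + traj.incident_stroke <= left_no_cvd + 1e-9


class TestSummaries:
    def test_mi_share_is_split_exactly(self, tparams, settings):
        traj = run_cohort(100_000, risk_to_cycle_prob(0.08), tparams, settings)
        s = summarize_events(traj, settings)
        share = s["acute_mi"] / (s["acute_mi"] + s["acute_stroke"])
        assert share == pytest.approx(0.55, abs=1e-12)

    def test_counts_scale_linearly_with_initial_size(self, tparams, settings):
        a = summarize_events(run_cohort(1_000, 0.002, tparams, settings), settings)
        b = summarize_events(run_cohort(10_000, 0.002, tparams, settings), settings)
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-9)

    def test_zero_event_run_has_zero_cvd_counts(self, tparams, settings):
        s = summarize_events(run_cohort(1_000, 0.0, tparams, settings), settings)
        assert s["acute_mi"] == s["acute_stroke"] == 0.0
        assert s["mi_deaths"] == s["stroke_deaths"] == 0.0

    def test_long_format_table(self, tparams, settings):
        traj = run_cohort(100, 0.001, tparams, settings)
        long = trajectory_to_long(traj)
        assert set(long.columns) == {"cycle", "state", "count"}
        assert len(long) == (settings.horizon_cycles + 1) * 8


class TestMicrosimulation:
    def _homogeneous_cohort(self, n, risk=0.08):
        import pandas as pd

        return pd.DataFrame(
            {
                "id": [f"P{i}" for i in range(n)],
                "age": 45.0,
                "sex": "F",
                "sbp": 140.0,
                "bmi": 25.0,
                "smoker": 0,
                "arm": "control",
                "risk10": risk,
            }
        )

    def test_same_seed_identical_trajectories(self, tparams, settings):
        cohort = self._homogeneous_cohort(500)
        a = run_microsim(cohort, tparams, settings, seed=11)
        b = run_microsim(cohort, tparams, settings, seed=11)
        assert np.array_equal(a.occupancy, b.occupancy)
        assert np.array_equal(a.deaths, b.deaths)

    def test_zero_risk_produces_no_events(self, tparams, settings):
        cohort = self._homogeneous_cohort(300, risk=0.0)
        traj, paths = run_microsim(cohort, tparams, settings, seed=3, return_paths=True)
        assert traj.incident.sum() == 0
        assert not np.isin(paths, [HealthState.ACUTE_MI, HealthState.ACUTE_STROKE]).any()

    def test_tunnel_never_lasts_two_cycles(self, tparams, settings):
        cohort = self._homogeneous_cohort(400, risk=0.5)
        _, paths = run_microsim(cohort, tparams, settings, seed=5, return_paths=True)
        for acute in (HealthState.ACUTE_MI, HealthState.ACUTE_STROKE):
            consecutive = (paths[:, :-1] == acute) & (paths[:, 1:] == acute)
            assert not consecutive.any()

    def test_missing_risk_rejected(self, tparams, settings):
        cohort = self._homogeneous_cohort(10).drop(columns=["risk10"])
        with pytest.raises(ValueError, match="risk10"):
            run_microsim(cohort, tparams, settings, seed=1)

    def test_aggregate_matches_cohort_solution_across_seeds(self, tparams, settings):
        """Monte-Carlo oracle check: total events from the
        microsimulation agree with the deterministic propagation within
        3 standard errors of the across-seed spread (>= 20 seeds)."""
        n = 2_000
        cohort = self._homogeneous_cohort(n)
        expected = run_cohort_from_patients(cohort, tparams, settings)
        expected_events = expected.incident.sum()
        totals = []
        for seed in range(20):
            traj = run_microsim(cohort, tparams, settings, seed=1_000 + seed)
            totals.append(traj.incident.sum())
        totals = np.asarray(totals, dtype=float)
        se = totals.std(ddof=1) / np.sqrt(len(totals))
        assert abs(totals.mean() - expected_events) < 3 * se + 1e-9
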