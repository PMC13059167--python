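"""Costing: ledger arithmetic, event/chronic/medication costs, markup
and access rules, and the three-way cost decomposition."""

import numpy as np
import pandas as pd
import pytest

from htncea import (
    CostInputs,
    ModelSettings,
    ScenarioSpec,
    default_scenarios,
    risk_to_cycle_prob,
    run_cohort,
)
from htncea.costing import (
    EXAMPLE_PATIENT_YEARS,
    LEDGER_COLUMNS,
    event_costs,
    example_ledger,
    medication_costs,
    per_patient_year_cost,
    program_costs,
    total_scenario_cost,
)


class TestPerPatientYear:
    def test_tag_filter_and_division(self):
        ledger = pd.DataFrame(
            [
                ("hr", "HR", "program", "control", "baseline", 500.0),
                ("cons", "consumables_travel_equipment", "program", "control", "baseline", 250.0),
                ("res", "HR", "research", "control", "baseline", 999.0),
            ],
            columns=LEDGER_COLUMNS,
        )
        rates = per_patient_year_cost(ledger, 250.0)
        assert rates["HR"] == 2.0
        assert rates["consumables_travel_equipment"] == 1.0
        assert rates["total"] == 3.0  # research excluded

    def test_example_ledger_reproduces_published_rates(self):
        ledger = example_ledger()
        cb = per_patient_year_cost(ledger, EXAMPLE_PATIENT_YEARS, "control", "baseline")
        cs = per_patient_year_cost(ledger, EXAMPLE_PATIENT_YEARS, "control", "sustainment")
        isus = per_patient_year_cost(ledger, EXAMPLE_PATIENT_YEARS, "intervention", "sustainment")
        assert cb["total"] == pytest.approx(2.46)
        assert cs["total"] == pytest.approx(7.07)
        assert isus["total"] == pytest.approx(7.86)
        # published per-patient-year increments
        assert cs["total"] - cb["total"] == pytest.approx(4.61)
        assert isus["total"] - cs["total"] == pytest.approx(0.79)

    def test_zero_patient_years_rejected(self):
        with pytest.raises(ZeroDivisionError):
            per_patient_year_cost(example_ledger(), 0.0)

    def test_unknown_tag_rejected(self):
        bad = example_ledger()
        bad.loc[0, "tag"] = "mystery"
        with pytest.raises(ValueError, match="tag"):
            per_patient_year_cost(bad, 100.0)


class TestEventCosts:
    def test_single_acute_mi_at_cycle_zero(self, tparams, costs):
        s = ModelSettings(horizon_cycles=1, annual_discount=0.0)
        params = type(tparams)(p_mi_split=1.0, p_background_death=0.0)
        traj = run_cohort(1.0, 1.0, params, s)
        ev = event_costs(traj, costs, s)
        assert ev["acute_base"] + ev["acute_markup"] == pytest.approx(
            547 * 0.2 * 1.27
        )
        assert ev["acute_base"] + ev["acute_markup"] == pytest.approx(138.94, abs=5e-3)

    def test_zero_access_zeroes_cv_care(self, tparams, settings):
        inputs = CostInputs(access_acute=0.0, access_chronic=0.0)
        traj = run_cohort(10_000, risk_to_cycle_prob(0.1), tparams, settings)
        ev = event_costs(traj, inputs, settings)
        assert all(v == 0.0 for v in ev.values())

    def test_no_events_no_cost(self, tparams, costs, settings):
        traj = run_cohort(10_000, 0.0, tparams, settings)
        ev = event_costs(traj, costs, settings)
        assert ev["acute_base"] == ev["chronic_base"] == 0.0


class TestMedicationAndProgram:
    def test_undiscounted_full_coverage_arithmetic(self, costs):
        # 100,000 alive for all 120 cycles at 8.2% coverage, r = 0
        s = ModelSettings(annual_discount=0.0)
        params = _deathless()
        traj = run_cohort(100_000, 0.0, params, s)
        med = medication_costs(traj, 0.082, costs, s)
        assert med == pytest.approx(100_000 * 17.50 * 0.082 * 10, rel=1e-12)

    def test_linear_in_coverage(self, tparams, costs, settings):
        traj = run_cohort(50_000, 0.0, tparams, settings)
        low = medication_costs(traj, 0.021, costs, settings)
        high = medication_costs(traj, 0.082, costs, settings)
        assert low / high == pytest.approx(0.021 / 0.082, rel=1e-12)
        assert medication_costs(traj, 0.0, costs, settings) == 0.0

    def test_discounting_reduces_program_cost(self, tparams):
        r0 = ModelSettings(annual_discount=0.0)
        r3 = ModelSettings(annual_discount=0.03)
        traj0 = run_cohort(10_000, 0.0, tparams, r0)
        assert program_costs(traj0, 7.07, r3) < program_costs(traj0, 7.07, r0)


def _deathless():
    from htncea import TransitionParameters

    return TransitionParameters(p_background_death=0.0)


class TestScenarioTotals:
    def test_decomposition_sums_to_total(self, tparams, costs, settings):
        traj = run_cohort(100_000, risk_to_cycle_prob(0.08), tparams, settings)
        scen = default_scenarios()["intervention_sustainment"]
        breakdown = total_scenario_cost(scen, traj, costs, settings)
        assert breakdown.total == pytest.approx(
            breakdown.direct + breakdown.indirect + breakdown.system_strengthening,
            abs=1e-6,
        )
        assert breakdown.system_strengthening > 0

    def test_status_quo_is_event_costs_only(self, tparams, costs, settings):
        traj = run_cohort(100_000, risk_to_cycle_prob(0.08), tparams, settings)
        scen = default_scenarios()["status_quo"]
        breakdown = total_scenario_cost(scen, traj, costs, settings)
        ev = event_costs(traj, costs, settings)
        scale = settings.population_scale / traj.initial_size
        assert breakdown.system_strengthening == 0.0
        assert breakdown.direct == pytest.approx(
            (ev["acute_base"] + ev["chronic_base"]) * scale
        )

    def test_homogeneous_in_population(self, tparams, costs, settings):
        scen = default_scenarios()["control_sustainment"]
        a = total_scenario_cost(
            scen, run_cohort(1_000, 0.001, tparams, settings), costs, settings
        )
        b = total_scenario_cost(
            scen, run_cohort(2_000, 0.001, tparams, settings), costs, settings
        )
        # per-100,000 reporting makes totals scale-invariant
        assert a.total == pytest.approx(b.total, rel=1e-9)

    def test_all_costs_nonnegative(self, fitted_results):
        scen = fitted_results.scenarios
        assert (scen[["cost_direct", "cost_indirect", "cost_system_strengthening"]] >= 0).all().all()
        assert np.allclose(
            scen["cost_total"],
            scen[["cost_direct", "cost_indirect", "cost_system_strengthening"]].sum(axis=1),
        )
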