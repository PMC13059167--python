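"""Sensitivity analysis: beta fitting, sampling supports, PSA
reproducibility, DSA behaviour, and CEAC properties."""

import numpy as np
import pytest
from scipy import stats

from htncea import ParamDistribution, fit_beta, sample_psa, ceac
from htncea.params import CEASettings, DomainError
from htncea.uncertainty import default_distributions, one_way_dsa


class TestBetaFit:
    @pytest.mark.parametrize(
        "mean,lo,hi",
        [(0.439, 0.405, 0.477), (0.101, 0.093, 0.103),
         (0.920, 0.782, 0.990), (0.266, 0.228, 0.295)],
    )
    def test_mean_matched_exactly(self, mean, lo, hi):
        a, b = fit_beta(mean, lo, hi)
        assert a > 0 and b > 0
        assert a / (a + b) == pytest.approx(mean, abs=1e-6)

    def test_symmetric_interval_gives_equal_shapes(self):
        a, b = fit_beta(0.5, 0.4, 0.6)
        assert a == pytest.approx(b)

    def test_quantiles_near_stated_interval(self):
        mean, lo, hi = 0.439, 0.405, 0.477
        a, b = fit_beta(mean, lo, hi)
        q_lo, q_hi = stats.beta.ppf([0.025, 0.975], a, b)
        width = hi - lo
        assert abs(q_lo - lo) < 0.2 * width
        assert abs(q_hi - hi) < 0.2 * width

    def test_ordering_violation_raises(self):
        with pytest.raises(DomainError):
            fit_beta(0.3, 0.4, 0.5)


class TestDistributions:
    def test_triangular_support_and_mean(self):
        dist = ParamDistribution("costs.acute_mi_cost", "triangular", (465, 547, 629))
        rng = np.random.default_rng(0)
        draws = np.array([dist.sample(rng) for _ in range(4_000)])
        assert draws.min() >= 465 and draws.max() <= 629
        assert draws.mean() == pytest.approx((465 + 547 + 629) / 3, abs=2.0)

    def test_degenerate_triangular_is_constant(self):
        dist = ParamDistribution("x", "triangular", (5.0, 5.0, 5.0))
        rng = np.random.default_rng(0)
        assert dist.sample(rng) == 5.0

    def test_all_defaults_sample_within_support(self, fitted_model):
        rng = np.random.default_rng(42)
        for dist in default_distributions(fitted_model.inputs):
            lo, hi = dist.support()
            for _ in range(50):
                assert lo <= dist.sample(rng) <= hi

    def test_unknown_kind_rejected(self):
        with pytest.raises(DomainError):
            ParamDistribution("x", "gamma", (1.0, 2.0))


@pytest.fixture(scope="module")
def psa_small(fitted_model):
    return sample_psa(
        fitted_model.cohort, fitted_model.life_table, fitted_model.inputs,
        n_draws=20, seed=5, mode="cohort",
    )


class TestPSA:
    def test_shape_one_row_per_draw_and_comparison(self, psa_small):
        assert len(psa_small) == 20 * 2
        assert set(psa_small["comparison"]) == {
            "intervention", "implementation_strategy",
        }

    def test_seeded_reproducibility(self, fitted_model, psa_small):
        again = sample_psa(
            fitted_model.cohort, fitted_model.life_table, fitted_model.inputs,
            n_draws=20, seed=5, mode="cohort",
        )
        assert np.allclose(
            psa_small.drop(columns="comparison").to_numpy(dtype=float),
            again.drop(columns="comparison").to_numpy(dtype=float),
        )

    def test_sampled_values_respect_supports(self, fitted_model, psa_small):
        for dist in default_distributions(fitted_model.inputs):
            lo, hi = dist.support()
            assert psa_small[dist.name].between(lo, hi).all()

    def test_degenerate_distributions_reproduce_base_case(self, fitted_model, fitted_results):
        c = fitted_model.inputs.costs
        degenerate = [
            ParamDistribution(
                "costs.acute_mi_cost", "triangular",
                (c.acute_mi_cost,) * 3,
            )
        ]
        psa = sample_psa(
            fitted_model.cohort, fitted_model.life_table, fitted_model.inputs,
            n_draws=1, seed=0, distributions=degenerate, mode="cohort",
        )
        base = fitted_results.comparisons["implementation_strategy"]
        row = psa[psa["comparison"] == "implementation_strategy"].iloc[0]
        assert row["delta_cost"] == pytest.approx(base.delta_cost, rel=1e-9)
        assert row["dalys_averted"] == pytest.approx(base.dalys_averted, rel=1e-9)

    def test_hybrid_mode_uses_common_random_numbers(self, fitted_model):
        """Within a draw the scenarios share one random stream, so the
        higher-risk scenario's events are a superset: DALYs averted are
        never negative."""
        psa = sample_psa(
            fitted_model.cohort, fitted_model.life_table, fitted_model.inputs,
            n_draws=8, seed=9, mode="hybrid",
        )
        assert (psa["dalys_averted"] >= 0).all()


class TestCEAC:
    def test_nondecreasing_when_all_draws_avert(self, fitted_model):
        psa = sample_psa(
            fitted_model.cohort, fitted_model.life_table, fitted_model.inputs,
            n_draws=15, seed=2, mode="cohort",
        )
        grid = np.linspace(10, 1_000, 25)
        curves = ceac(psa, wtp_grid=grid)
        for _, grp in curves.groupby("comparison"):
            p = grp.sort_values("wtp")["probability_cost_effective"].to_numpy()
            assert np.all(np.diff(p) >= 0)
            assert np.all((p >= 0) & (p <= 1))

    def test_limits_of_the_wtp_axis(self, fitted_model):
        psa = sample_psa(
            fitted_model.cohort, fitted_model.life_table, fitted_model.inputs,
            n_draws=10, seed=3, mode="cohort",
        )
        curves = ceac(psa, wtp_grid=np.array([1e-6, 1e9]))
        for _, grp in curves.groupby("comparison"):
            low = grp[grp["wtp"] < 1]["probability_cost_effective"].iloc[0]
            high = grp[grp["wtp"] > 1]["probability_cost_effective"].iloc[0]
            # tiny WTP cannot justify any positive cost increment
            assert low == 0.0
            # huge WTP accepts every draw that averts DALYs
            averting = (psa[psa["comparison"] == grp["comparison"].iloc[0]]
                        ["dalys_averted"] > 0).mean()
            assert high == pytest.approx(averting)

    def test_default_grid_comes_from_settings(self, fitted_model):
        psa = sample_psa(
            fitted_model.cohort, fitted_model.life_table, fitted_model.inputs,
            n_draws=5, seed=4, mode="cohort",
        )
        curves = ceac(psa, settings=CEASettings())
        assert sorted(curves["wtp"].unique()) == [162.5, 325.0, 647.0]


class TestOneWayDSA:
    def test_degenerate_range_equals_base(self, fitted_model):
        base_access = fitted_model.inputs.costs.access_acute
        table = one_way_dsa(
            fitted_model.cohort, fitted_model.life_table, fitted_model.inputs,
            "costs.access_acute", base_access, base_access,
        )
        for _, row in table.iterrows():
            assert row["icer_low"] == pytest.approx(row["icer_base"])
            assert row["icer_high"] == pytest.approx(row["icer_base"])

    def test_access_range_yields_finite_icers(self, fitted_model):
        table = one_way_dsa(
            fitted_model.cohort, fitted_model.life_table, fitted_model.inputs,
            "costs.access_acute", 0.0, 0.80,
        )
        assert np.isfinite(table[["icer_low", "icer_high", "icer_base"]].to_numpy(float)).all()

    def test_medication_cost_moves_intervention_icer_more_than_weights(self, fitted_model):
        """Tornado ordering: antihypertensive medication cost is a larger
        driver of the intervention ICER than any disability weight."""
        med = one_way_dsa(
            fitted_model.cohort, fitted_model.life_table, fitted_model.inputs,
            "costs.htn_med_annual", 0.8 * 17.5, 1.2 * 17.5,
        )
        w = fitted_model.inputs.weights
        weight_spans = []
        for name in ("acute_mi", "chronic_ihd", "acute_stroke", "post_stroke"):
            lo, hi = getattr(w, f"{name}_interval")
            t = one_way_dsa(
                fitted_model.cohort, fitted_model.life_table, fitted_model.inputs,
                f"weights.{name}", lo, hi,
            )
            weight_spans.append(
                t.set_index("comparison").loc["intervention", "span"]
            )
        med_span = med.set_index("comparison").loc["intervention", "span"]
        assert med_span > max(weight_spans)

    def test_unknown_parameter_rejected(self, fitted_model):
        with pytest.raises(KeyError):
            one_way_dsa(
                fitted_model.cohort, fitted_model.life_table, fitted_model.inputs,
                "costs.nonexistent", 0.0, 1.0,
            )

    def test_inverted_range_rejected(self, fitted_model):
        with pytest.raises(DomainError):
            one_way_dsa(
                fitted_model.cohort, fitted_model.life_table, fitted_model.inputs,
                "costs.access_acute", 0.5, 0.1,
            )
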