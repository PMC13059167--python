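"""Deterministic and probabilistic sensitivity analysis.

One-way DSA re-evaluates the full deterministic model at a parameter's
low and high values (tornado data). The PSA draws costs from triangular
distributions (printed min / central / max, central treated as the
mode), disability weights from beta distributions moment-matched to the
printed mean and 95% interval (SD = interval width / 3.92), and
transition probabilities from uniform ranges of +/-20% around base values
clipped to [0, 1]; draws are joint and independent.

Two PSA modes:

* ``cohort`` — the deterministic cohort engine per parameter draw
  (pure parameter uncertainty); used for the implementation-strategy
  comparison, whose published uncertainty interval is parameter-driven.
* ``hybrid`` — a seeded 334-patient microsimulation per scenario per
  draw with common random numbers across scenarios within a draw
  (334 patients x 3 scenarios x 100 draws > 100,000 simulated paths),
  adding patient-level heterogeneity; used for the intervention
  comparison.

The CEAC reports, at each willingness-to-pay, the fraction of draws with
positive net monetary benefit (wtp x DALYs averted - incremental cost),
which is robust to negative increments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import BASE_COMPARISONS, CEResult, compare_scenarios, icer
from .costing import total_scenario_cost
from .engine import run_microsim
from .outcomes import LifeTable, compute_dalys
from .params import CEASettings, DomainError, ModelInputs


@dataclass(frozen=True)
class ParamDistribution:
    """One varied parameter: ``kind`` in {triangular, beta, uniform}.

    args: (min, mode, max) for triangular; (mean, lower95, upper95) for
    beta (shapes fitted internally); (low, high) for uniform.
    """

    name: str
    kind: str
    args: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind == "triangular":
            lo, mode, hi = self.args
            if not lo <= mode <= hi:
                raise DomainError(f"{self.name}: need min <= mode <= max")
        elif self.kind == "beta":
            fit_beta(*self.args)  # validates ordering
        elif self.kind == "uniform":
            lo, hi = self.args
            if not lo <= hi:
                raise DomainError(f"{self.name}: need low <= high")
        else:
            raise DomainError(f"{self.name}: unknown distribution kind {self.kind!r}")

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "triangular":
            lo, mode, hi = self.args
            if lo == hi:
                return lo
            return float(rng.triangular(lo, mode, hi))
        if self.kind == "beta":
            a, b = fit_beta(*self.args)
            return float(rng.beta(a, b))
        lo, hi = self.args
        return float(rng.uniform(lo, hi))

    def support(self) -> tuple[float, float]:
        if self.kind == "beta":
            return (0.0, 1.0)
        return (self.args[0], self.args[-1])


def fit_beta(mean: float, lower95: float, upper95: float) -> tuple[float, float]:
    """Beta shapes by moment matching: the SD is inferred from the 95%
    interval as ``(upper95 - lower95) / 3.92``; the fitted mean is exact."""
    if not 0.0 < lower95 <= mean <= upper95 < 1.0:
        raise DomainError(
            f"need 0 < lower95 <= mean <= upper95 < 1, got "
            f"({mean}, {lower95}, {upper95})"
        )
    sd = (upper95 - lower95) / 3.92
    var = sd**2
    if var >= mean * (1.0 - mean):
        raise DomainError("implied variance too large for a beta distribution")
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def default_distributions(inputs: ModelInputs) -> list[ParamDistribution]:
    """The base-case PSA parameter set."""
    c, w, t = inputs.costs, inputs.weights, inputs.transitions
    dists = [
        ParamDistribution("costs.acute_mi_cost", "triangular",
                          (c.acute_mi_cost_interval[0], c.acute_mi_cost,
                           c.acute_mi_cost_interval[1])),
        ParamDistribution("costs.chronic_ihd_cost_annual", "triangular",
                          (c.chronic_ihd_cost_interval[0], c.chronic_ihd_cost_annual,
                           c.chronic_ihd_cost_interval[1])),
        ParamDistribution("costs.acute_stroke_cost", "triangular",
                          (c.acute_stroke_cost_interval[0], c.acute_stroke_cost,
                           c.acute_stroke_cost_interval[1])),
        ParamDistribution("costs.post_stroke_cost_annual", "triangular",
                          (c.post_stroke_cost_interval[0], c.post_stroke_cost_annual,
                           c.post_stroke_cost_interval[1])),
        ParamDistribution("costs.htn_med_annual", "uniform",
                          (0.8 * c.htn_med_annual, 1.2 * c.htn_med_annual)),
        ParamDistribution("costs.access_acute", "triangular",
                          (c.access_acute_range[0], c.access_acute,
                           c.access_acute_range[1])),
        ParamDistribution("weights.acute_mi", "beta",
                          (w.acute_mi, *w.acute_mi_interval)),
        ParamDistribution("weights.chronic_ihd", "beta",
                          (w.chronic_ihd, *w.chronic_ihd_interval)),
        ParamDistribution("weights.acute_stroke", "beta",
                          (w.acute_stroke, *w.acute_stroke_interval)),
        ParamDistribution("weights.post_stroke", "beta",
                          (w.post_stroke, *w.post_stroke_interval)),
    ]
    for name in (
        "p_acute_mi_death", "p_chronic_ihd_death", "p_acute_stroke_death",
        "p_post_stroke_death", "p_background_death",
    ):
        base = getattr(t, name)
        dists.append(
            ParamDistribution(
                f"transitions.{name}", "uniform",
                (max(0.0, 0.8 * base), min(1.0, 1.2 * base)),
            )
        )
    return dists


def _overrides_from_draw(
    inputs: ModelInputs, sampled: dict[str, float]
) -> ModelInputs:
    overrides: dict[str, object] = {}
    for name, value in sampled.items():
        overrides[name] = value
        block, _, field_name = name.partition(".")
        if block == "weights":
            lo, hi = getattr(inputs.weights, field_name + "_interval")
            overrides[f"weights.{field_name}_interval"] = (
                min(lo, value), max(hi, value),
            )
    return inputs.with_overrides(overrides)


def _scenario_names(comparisons) -> tuple[str, ...]:
    names: list[str] = []
    for _, a, b in comparisons:
        for n in (a, b):
            if n not in names:
                names.append(n)
    return tuple(names)


def sample_psa(
    cohort: pd.DataFrame,
    life_table: LifeTable,
    inputs: ModelInputs,
    n_draws: int = 100,
    seed: int = 0,
    distributions: list[ParamDistribution] | None = None,
    mode: str = "cohort",
    comparisons=BASE_COMPARISONS,
) -> pd.DataFrame:
    """Run the PSA: one full model evaluation per parameter draw.

    Returns a long table with one row per (draw, comparison) carrying the
    sampled parameter values, per-scenario costs and DALYs, and the
    increments. Seeded and reproducible; in ``hybrid`` mode each draw's
    scenarios share one microsimulation random stream (common random
    numbers).
    """
    if n_draws < 1:
        raise DomainError("n_draws must be >= 1")
    if mode not in ("cohort", "hybrid"):
        raise DomainError(f"unknown PSA mode {mode!r}")
    dists = distributions if distributions is not None else default_distributions(inputs)
    rng = np.random.default_rng(seed)
    names = _scenario_names(comparisons)
    rows = []
    for draw in range(n_draws):
        sampled = {d.name: d.sample(rng) for d in dists}
        draw_inputs = _overrides_from_draw(inputs, sampled)
        sim_seed = int(rng.integers(2**31))
        results = {}
        for scen_name in names:
            scen = draw_inputs.scenarios[scen_name]
            if mode == "cohort":
                from .engine import run_cohort_from_patients

                traj = run_cohort_from_patients(
                    cohort, draw_inputs.transitions, draw_inputs.settings,
                    risk_reduction=scen.risk_reduction,
                )
            else:
                traj = run_microsim(
                    cohort, draw_inputs.transitions, draw_inputs.settings,
                    seed=sim_seed, risk_reduction=scen.risk_reduction,
                )
            outcome = compute_dalys(
                traj, life_table, draw_inputs.weights, draw_inputs.settings,
                scenario=scen_name,
            )
            cost = total_scenario_cost(
                scen, traj, draw_inputs.costs, draw_inputs.settings
            )
            results[scen_name] = (cost.total, outcome.dalys)
        for label, comp, interv in comparisons:
            rows.append(
                {
                    "draw": draw,
                    "comparison": label,
                    **sampled,
                    "cost_comparator": results[comp][0],
                    "dalys_comparator": results[comp][1],
                    "cost_intervention": results[interv][0],
                    "dalys_intervention": results[interv][1],
                    "delta_cost": results[interv][0] - results[comp][0],
                    "dalys_averted": results[comp][1] - results[interv][1],
                }
            )
    return pd.DataFrame(rows)


def ceac(
    psa_results: pd.DataFrame,
    settings: CEASettings | None = None,
    wtp_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve per comparison: fraction of
    draws with positive net monetary benefit at each willingness-to-pay."""
    settings = settings or CEASettings()
    grid = np.asarray(wtp_grid if wtp_grid is not None else settings.wtp_grid, dtype=float)
    rows = []
    for label, grp in psa_results.groupby("comparison", sort=False):
        averted = grp["dalys_averted"].to_numpy()
        dcost = grp["delta_cost"].to_numpy()
        for w in grid:
            nmb = w * averted - dcost
            rows.append(
                {
                    "comparison": label,
                    "wtp": float(w),
                    "probability_cost_effective": float(np.mean(nmb > 0)),
                }
            )
    return pd.DataFrame(rows)


def one_way_dsa(
    cohort: pd.DataFrame,
    life_table: LifeTable,
    inputs: ModelInputs,
    parameter: str,
    low: float,
    high: float,
    comparisons=BASE_COMPARISONS,
) -> pd.DataFrame:
    """One-way deterministic sensitivity analysis for one parameter.

    Three full deterministic evaluations (base, low, high); returns one
    row per comparison with the base ICER and the ICERs at each end,
    plus the tornado half-widths ``|icer - base|``.
    """
    if low > high:
        raise DomainError("need low <= high")

    def evaluate(model_inputs: ModelInputs) -> dict[str, CEResult]:
        from .cea import run_scenarios

        table = run_scenarios(
            cohort, life_table, model_inputs,
            scenario_names=_scenario_names(comparisons),
        )
        return compare_scenarios(table, comparisons)

    base = evaluate(inputs)
    at_low = evaluate(_overrides_from_draw(inputs, {parameter: low}))
    at_high = evaluate(_overrides_from_draw(inputs, {parameter: high}))
    rows = []
    for label, _, _ in comparisons:
        b, lo_r, hi_r = base[label], at_low[label], at_high[label]
        rows.append(
            {
                "comparison": label,
                "parameter": parameter,
                "low": low,
                "high": high,
                "icer_base": b.icer,
                "icer_low": lo_r.icer,
                "icer_high": hi_r.icer,
                "span": (
                    abs(hi_r.icer - lo_r.icer)
                    if lo_r.icer is not None and hi_r.icer is not None
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


#: default one-way DSA parameter ranges (printed ranges where available,
#: otherwise +/-20% around base values)
def default_dsa_ranges(inputs: ModelInputs) -> dict[str, tuple[float, float]]:
    c, w, t = inputs.costs, inputs.weights, inputs.transitions
    ranges = {
        "costs.acute_mi_cost": c.acute_mi_cost_interval,
        "costs.chronic_ihd_cost_annual": c.chronic_ihd_cost_interval,
        "costs.acute_stroke_cost": c.acute_stroke_cost_interval,
        "costs.post_stroke_cost_annual": c.post_stroke_cost_interval,
        "costs.htn_med_annual": (0.8 * c.htn_med_annual, 1.2 * c.htn_med_annual),
        "costs.access_acute": c.access_acute_range,
        "weights.acute_mi": w.acute_mi_interval,
        "weights.chronic_ihd": w.chronic_ihd_interval,
        "weights.acute_stroke": w.acute_stroke_interval,
        "weights.post_stroke": w.post_stroke_interval,
        "scenarios.intervention_sustainment.ppy_saia_cost": (
            0.8 * inputs.scenarios["intervention_sustainment"].ppy_saia_cost,
            1.2 * inputs.scenarios["intervention_sustainment"].ppy_saia_cost,
        ),
    }
    for name in ("p_acute_mi_death", "p_acute_stroke_death"):
        base = getattr(t, name)
        ranges[f"transitions.{name}"] = (0.8 * base, min(1.0, 1.2 * base))
    return ranges
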