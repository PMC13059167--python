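"""Scenario runs and incremental cost-effectiveness.

Two base-case comparisons: the hypertension intervention
(control_sustainment vs control_baseline) and the implementation
strategy (intervention_sustainment vs control_sustainment). ICER =
incremental cost / DALYs averted when both increments are positive;
dominance flags otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .costing import total_scenario_cost
from .engine import run_cohort_from_patients
from .outcomes import LifeTable, compute_dalys
from .params import ModelInputs

#: (label, comparator scenario, intervention scenario)
BASE_COMPARISONS = (
    ("intervention", "control_baseline", "control_sustainment"),
    ("implementation_strategy", "control_sustainment", "intervention_sustainment"),
)


@dataclass(frozen=True)
class CEResult:
    """One incremental comparison.

    ``classification`` is one of ``icer`` (both increments positive, or
    the south-west trade-off of savings against DALYs lost), ``dominant``
    (cheaper, at least as effective), ``dominated`` (costlier, no more
    effective) or ``undefined`` (no DALY increment to divide by).
    """

    comparator: str
    intervention: str
    delta_cost: float
    dalys_averted: float
    icer: float | None
    classification: str

    def cost_effective(self, wtp: float) -> bool:
        """Net-monetary-benefit test at willingness-to-pay ``wtp``:
        ``wtp * DALYs averted - incremental cost > 0``."""
        return wtp * self.dalys_averted - self.delta_cost > 0


def icer(
    cost_a: float,
    dalys_a: float,
    cost_b: float,
    dalys_b: float,
    comparator: str = "comparator",
    intervention: str = "intervention",
) -> CEResult:
    """Incremental comparison of run b (intervention) against run a
    (comparator): ``delta_cost / dalys_averted`` with dominance handling.
    Inputs must share the same population scale."""
    delta_cost = cost_b - cost_a
    averted = dalys_a - dalys_b
    if delta_cost > 0 and averted > 0:
        value, cls = delta_cost / averted, "icer"
    elif delta_cost < 0 and averted < 0:
        value, cls = delta_cost / averted, "icer"
    elif averted == 0 and delta_cost == 0:
        value, cls = None, "undefined"
    elif averted == 0:
        value, cls = None, "undefined"
    elif delta_cost <= 0 and averted > 0:
        value, cls = None, "dominant"
    else:
        value, cls = None, "dominated"
    return CEResult(
        comparator=comparator,
        intervention=intervention,
        delta_cost=delta_cost,
        dalys_averted=averted,
        icer=value,
        classification=cls,
    )


def run_scenarios(
    cohort: pd.DataFrame,
    life_table: LifeTable,
    inputs: ModelInputs,
    scenario_names: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Deterministic cohort-mode run of each scenario on a shared cohort.

    Returns one row per scenario with events, deaths, discounted YLL,
    YLD, DALYs and the three cost categories, all per the reporting
    population (100,000 by default).
    """
    names = scenario_names or tuple(inputs.scenarios)
    unknown = [n for n in names if n not in inputs.scenarios]
    if unknown:
        raise KeyError(f"unknown scenario name(s): {unknown}")
    rows = []
    for name in names:
        scen = inputs.scenarios[name]
        traj = run_cohort_from_patients(
            cohort, inputs.transitions, inputs.settings,
            risk_reduction=scen.risk_reduction,
        )
        outcome = compute_dalys(
            traj, life_table, inputs.weights, inputs.settings, scenario=name
        )
        costs = total_scenario_cost(scen, traj, inputs.costs, inputs.settings)
        rows.append(
            {
                "scenario": name,
                **outcome.events,
                "yll": outcome.yll,
                "yld": outcome.yld,
                "dalys": outcome.dalys,
                "cost_direct": costs.direct,
                "cost_indirect": costs.indirect,
                "cost_system_strengthening": costs.system_strengthening,
                "cost_total": costs.total,
            }
        )
    return pd.DataFrame(rows).set_index("scenario")


def compare_scenarios(
    scenario_table: pd.DataFrame,
    comparisons=BASE_COMPARISONS,
) -> dict[str, CEResult]:
    """Both base-case ICERs from a :func:`run_scenarios` table."""
    out = {}
    for label, comp, interv in comparisons:
        out[label] = icer(
            scenario_table.loc[comp, "cost_total"],
            scenario_table.loc[comp, "dalys"],
            scenario_table.loc[interv, "cost_total"],
            scenario_table.loc[interv, "dalys"],
            comparator=comp,
            intervention=interv,
        )
    return out
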