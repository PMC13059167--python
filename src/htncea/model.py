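"""Model / Results facade over the functional modules.

``CostEffectivenessModel`` bundles a patient cohort, a life table and the
full parameter set; ``fit()`` runs the deterministic cohort-mode
scenarios and returns a ``CostEffectivenessResults`` carrying the
scenario table, both incremental comparisons, and methods for
sensitivity analysis (``psa``, ``dsa``, ``ceac``) and plotting.

Example
-------
>>> from htncea.model import CostEffectivenessModel
>>> model = CostEffectivenessModel.from_synthetic(seed=1)
>>> res = model.fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import BASE_COMPARISONS, CEResult, compare_scenarios, run_scenarios
from .outcomes import LifeTable
from .params import CEASettings, ModelInputs
from .uncertainty import ParamDistribution, ceac as _ceac, one_way_dsa, sample_psa


class CostEffectivenessModel:
    """Decision-analytic cost-effectiveness model of hypertension care
    among people living with HIV.

    Parameters
    ----------
    cohort
        Patient table with columns id, age, sex, sbp, bmi, smoker, arm,
        risk10 (baseline 10-year cardiovascular risk in [0, 1]).
    life_table
        Residual life expectancy by sex and age, for YLL.
    inputs
        Full parameter bundle (transition probabilities, disability
        weights, unit costs, scenario definitions, settings).
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        life_table: LifeTable,
        inputs: ModelInputs | None = None,
    ):
        if "risk10" not in cohort.columns:
            raise ValueError("cohort must carry a risk10 column")
        self.cohort = cohort.reset_index(drop=True)
        self.life_table = life_table
        self.inputs = inputs or ModelInputs()

    @classmethod
    def from_dataframe(
        cls,
        cohort: pd.DataFrame,
        life_table: LifeTable,
        chart=None,
        inputs: ModelInputs | None = None,
    ) -> "CostEffectivenessModel":
        """Build from a cohort table; if ``chart`` is given and risk10 is
        absent, risks are assigned by chart lookup."""
        if "risk10" not in cohort.columns:
            if chart is None:
                raise ValueError("provide a risk chart or a risk10 column")
            from .synthetic import assign_risk

            cohort = cohort.copy()
            cohort["risk10"] = assign_risk(cohort, chart)
        return cls(cohort, life_table, inputs)

    @classmethod
    def from_synthetic(
        cls,
        seed: int,
        target_events_per_100k: float = 7_980.0,
        inputs: ModelInputs | None = None,
        spec=None,
    ) -> "CostEffectivenessModel":
        """Fully synthetic, calibrated study: the risk-chart intercept is
        tuned so the cohort's 10-year control-baseline run reproduces the
        target cumulative first-event count (default 7,980 per 100,000)."""
        from .synthetic import calibrated_cohort

        inputs = inputs or ModelInputs()
        cohort, chart, life = calibrated_cohort(
            seed, target_events_per_100k, spec=spec,
            params=inputs.transitions, settings=inputs.settings,
        )
        model = cls(cohort, life, inputs)
        model.chart = chart
        return model

    def fit(self, scenario_names: tuple[str, ...] | None = None) -> "CostEffectivenessResults":
        """Run every scenario deterministically and assemble results."""
        table = run_scenarios(
            self.cohort, self.life_table, self.inputs, scenario_names
        )
        comparisons = {}
        if scenario_names is None:
            comparisons = compare_scenarios(table)
        return CostEffectivenessResults(model=self, scenarios=table, comparisons=comparisons)


@dataclass
class CostEffectivenessResults:
    """Fitted scenario outcomes and incremental comparisons."""

    model: CostEffectivenessModel
    scenarios: pd.DataFrame
    comparisons: dict[str, CEResult] = field(default_factory=dict)

    @property
    def icers(self) -> pd.DataFrame:
        rows = [
            {
                "comparison": label,
                "comparator": r.comparator,
                "intervention": r.intervention,
                "delta_cost": r.delta_cost,
                "dalys_averted": r.dalys_averted,
                "icer": r.icer,
                "classification": r.classification,
            }
            for label, r in self.comparisons.items()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable results table (per 100,000 population)."""
        scen = self.scenarios.copy()
        cols = [
            "acute_mi", "acute_stroke", "mi_deaths", "stroke_deaths",
            "dalys", "cost_total",
        ]
        lines = [
            "Cost-effectiveness of hypertension care among PLHIV",
            f"(per {self.model.inputs.settings.population_scale:,.0f} population, "
            f"{self.model.inputs.settings.horizon_cycles} monthly cycles, "
            f"{self.model.inputs.settings.annual_discount:.0%} annual discount)",
            "",
            scen[cols].round(1).to_string(),
            "",
        ]
        for label, r in self.comparisons.items():
            icer_txt = f"${r.icer:,.2f}/DALY averted" if r.icer is not None else r.classification
            lines.append(
                f"{label}: {r.intervention} vs {r.comparator} -> "
                f"dCost ${r.delta_cost:,.0f}, DALYs averted {r.dalys_averted:,.1f}, "
                f"ICER {icer_txt}"
            )
        return "\n".join(lines)

    # ---- uncertainty -------------------------------------------------
    def psa(
        self,
        n_draws: int = 100,
        seed: int = 0,
        mode: str = "cohort",
        distributions: list[ParamDistribution] | None = None,
        comparisons=BASE_COMPARISONS,
    ) -> pd.DataFrame:
        return sample_psa(
            self.model.cohort, self.model.life_table, self.model.inputs,
            n_draws=n_draws, seed=seed, distributions=distributions,
            mode=mode, comparisons=comparisons,
        )

    def ceac(
        self,
        psa_results: pd.DataFrame,
        wtp_grid: np.ndarray | None = None,
        settings: CEASettings | None = None,
    ) -> pd.DataFrame:
        return _ceac(psa_results, settings=settings, wtp_grid=wtp_grid)

    def dsa(self, parameter: str, low: float, high: float) -> pd.DataFrame:
        return one_way_dsa(
            self.model.cohort, self.model.life_table, self.model.inputs,
            parameter, low, high,
        )

    def plot_ceac(self, ceac_table: pd.DataFrame, ax=None):
        """Probability-cost-effective vs willingness-to-pay, one line per
        comparison."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for label, grp in ceac_table.groupby("comparison", sort=False):
            ax.plot(grp["wtp"], grp["probability_cost_effective"], marker="o", label=label)
        ax.set_xlabel("Willingness to pay (USD per DALY averted)")
        ax.set_ylabel("Probability cost-effective")
        ax.set_ylim(-0.02, 1.02)
        ax.legend()
        return ax

    def plot_tornado(self, dsa_tables: list[pd.DataFrame], comparison: str, ax=None):
        """Tornado plot from a list of one-way DSA tables."""
        import matplotlib.pyplot as plt

        rows = pd.concat(dsa_tables, ignore_index=True)
        rows = rows[rows["comparison"] == comparison].dropna(subset=["span"])
        rows = rows.sort_values("span")
        if ax is None:
            _, ax = plt.subplots()
        base = rows["icer_base"].iloc[0] if len(rows) else 0.0
        for i, (_, r) in enumerate(rows.iterrows()):
            ax.barh(i, r["icer_high"] - base, left=base, color="tab:orange")
            ax.barh(i, r["icer_low"] - base, left=base, color="tab:blue")
        ax.set_yticks(range(len(rows)), rows["parameter"])
        ax.axvline(base, ls="--", color="k")
        ax.set_xlabel("ICER (USD per DALY averted)")
        return ax
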