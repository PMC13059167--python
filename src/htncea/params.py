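"""Shared parameter containers and their documented defaults.

Every default in this module is a base-case model input: trial-derived
effectiveness (within-arm 10-year cardiovascular risk reductions),
GBD/WHO-sourced monthly transition probabilities and annual disability
weights, unit costs in 2023 USD, and the modelling conventions (monthly
cycles, 10-year horizon, 3% annual discounting, results per 100,000
people living with HIV in hypertension care).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping


class DomainError(ValueError):
    """A parameter value lies outside its documented domain."""


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise DomainError(f"{name} must be a probability in [0, 1], got {value!r}")


def _check_nonneg(name: str, value: float) -> None:
    if value < 0.0:
        raise DomainError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class ModelSettings:
    """Global simulation conventions.

    horizon_cycles
        Number of monthly cycles simulated (120 = 10 years).
    annual_discount
        Annual discount rate applied to both costs and health outcomes.
    population_scale
        Reporting denominator: results are rescaled to this starting
        population (100,000 PLHIV seeking hypertension care).
    """

    horizon_cycles: int = 120
    annual_discount: float = 0.03
    population_scale: float = 100_000.0
    cycles_per_year: int = 12

    def __post_init__(self) -> None:
        if self.horizon_cycles < 0:
            raise DomainError("horizon_cycles must be >= 0")
        if self.annual_discount < 0:
            raise DomainError("annual_discount must be >= 0")
        if self.population_scale <= 0:
            raise DomainError("population_scale must be > 0")


@dataclass(frozen=True)
class RiskMappingParams:
    """Blood-pressure-to-risk mapping: each ``step_mmhg`` of sustained
    systolic BP reduction multiplies cardiovascular event risk by
    ``rr_per_step`` (default 0.90, i.e. ~10% risk reduction per 5 mmHg)."""

    rr_per_step: float = 0.90
    step_mmhg: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 < self.rr_per_step <= 1.0:
            raise DomainError("rr_per_step must be in (0, 1]")
        if self.step_mmhg <= 0:
            raise DomainError("step_mmhg must be > 0")


@dataclass(frozen=True)
class TransitionParameters:
    """Monthly transition probabilities and the first-event cause split.

    Acute case fatalities (``p_acute_mi_death``, ``p_acute_stroke_death``)
    apply during the single tunnel cycle; chronic-state and background
    probabilities apply every cycle.
    """

    p_mi_split: float = 0.55
    p_acute_mi_death: float = 0.65
    p_chronic_ihd_death: float = 0.0034
    p_acute_stroke_death: float = 0.38
    p_post_stroke_death: float = 0.0043
    p_background_death: float = 0.0018

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_prob(f.name, getattr(self, f.name))

    @property
    def p_stroke_split(self) -> float:
        return 1.0 - self.p_mi_split


@dataclass(frozen=True)
class DisabilityWeights:
    """Annual disability weights with 95% uncertainty intervals."""

    acute_mi: float = 0.439
    acute_mi_interval: tuple[float, float] = (0.405, 0.477)
    chronic_ihd: float = 0.101
    chronic_ihd_interval: tuple[float, float] = (0.093, 0.103)
    acute_stroke: float = 0.920
    acute_stroke_interval: tuple[float, float] = (0.782, 0.990)
    post_stroke: float = 0.266
    post_stroke_interval: tuple[float, float] = (0.228, 0.295)

    def __post_init__(self) -> None:
        for name in ("acute_mi", "chronic_ihd", "acute_stroke", "post_stroke"):
            w = getattr(self, name)
            _check_prob(name, w)
            lo, hi = getattr(self, name + "_interval")
            if not lo <= w <= hi:
                raise DomainError(
                    f"{name} interval ({lo}, {hi}) does not bracket the mean {w}"
                )


@dataclass(frozen=True)
class CostInputs:
    """Unit costs (2023 USD), access proportions, and facility markups.

    One-time acute costs are incurred at the event cycle; annual chronic
    costs accrue per occupied month. ``access_acute`` / ``access_chronic``
    are the proportions of patients assumed to reach (and hence be billed
    for) acute and chronic cardiovascular care. Facility indirect costs are
    a 27% markup on inpatient (acute) care and 7.4% on outpatient
    (chronic) care.
    """

    acute_mi_cost: float = 547.0
    acute_mi_cost_interval: tuple[float, float] = (465.0, 629.0)
    chronic_ihd_cost_annual: float = 12.0
    chronic_ihd_cost_interval: tuple[float, float] = (10.0, 14.0)
    acute_stroke_cost: float = 317.0
    acute_stroke_cost_interval: tuple[float, float] = (265.0, 365.0)
    post_stroke_cost_annual: float = 14.0
    post_stroke_cost_interval: tuple[float, float] = (12.0, 16.0)
    htn_med_annual: float = 17.50
    access_acute: float = 0.20
    access_acute_range: tuple[float, float] = (0.0, 0.80)
    access_chronic: float = 0.20
    markup_outpatient: float = 0.074
    markup_inpatient: float = 0.27

    def __post_init__(self) -> None:
        for name in (
            "acute_mi_cost",
            "chronic_ihd_cost_annual",
            "acute_stroke_cost",
            "post_stroke_cost_annual",
            "htn_med_annual",
            "markup_outpatient",
            "markup_inpatient",
        ):
            _check_nonneg(name, getattr(self, name))
        _check_prob("access_acute", self.access_acute)
        _check_prob("access_chronic", self.access_chronic)


@dataclass(frozen=True)
class ScenarioSpec:
    """One modelled screening/treatment scenario.

    risk_reduction
        Proportional reduction applied to each patient's baseline 10-year
        cardiovascular risk (0, 0.293, or 0.403 for the named scenarios).
    treatment_coverage
        Proportion of the cohort on antihypertensive medication.
    ppy_program_cost
        Program (screening/treatment delivery) cost per patient-year, USD.
    ppy_saia_cost
        System-strengthening (SAIA implementation strategy) cost per
        patient-year, USD; nonzero only when the strategy is deployed.
    """

    name: str
    risk_reduction: float = 0.0
    treatment_coverage: float = 0.0
    ppy_program_cost: float = 0.0
    ppy_saia_cost: float = 0.0

    def __post_init__(self) -> None:
        if not self.risk_reduction < 1.0:
            raise DomainError("risk_reduction must be < 1")
        _check_prob("treatment_coverage", self.treatment_coverage)
        _check_nonneg("ppy_program_cost", self.ppy_program_cost)
        _check_nonneg("ppy_saia_cost", self.ppy_saia_cost)

    @property
    def includes_saia(self) -> bool:
        return self.ppy_saia_cost > 0


def default_scenarios() -> dict[str, ScenarioSpec]:
    """The four base-case scenarios.

    The intervention comparison is control_sustainment vs control_baseline;
    the implementation-strategy comparison is intervention_sustainment vs
    control_sustainment. status_quo is a do-nothing reference with no
    screening program or treatment.
    """
    return {
        "status_quo": ScenarioSpec("status_quo"),
        "control_baseline": ScenarioSpec(
            "control_baseline",
            risk_reduction=0.0,
            treatment_coverage=0.021,
            ppy_program_cost=2.46,
        ),
        "control_sustainment": ScenarioSpec(
            "control_sustainment",
            risk_reduction=0.293,
            treatment_coverage=0.082,
            ppy_program_cost=7.07,
        ),
        "intervention_sustainment": ScenarioSpec(
            "intervention_sustainment",
            risk_reduction=0.403,
            treatment_coverage=0.082,
            ppy_program_cost=7.07,
            ppy_saia_cost=0.79,
        ),
    }


@dataclass(frozen=True)
class CEASettings:
    """Willingness-to-pay grid, USD per DALY averted (0.25x, 0.5x, 1x
    Mozambique GDP per capita)."""

    wtp_grid: tuple[float, ...] = (162.5, 325.0, 647.0)
    wtp_threshold: float = 647.0

    def __post_init__(self) -> None:
        grid = self.wtp_grid
        if any(w <= 0 for w in grid) or any(
            b <= a for a, b in zip(grid, grid[1:])
        ):
            raise DomainError("wtp_grid must be strictly increasing and positive")


@dataclass(frozen=True)
class ModelInputs:
    """Bundle of every parameter block a full model run needs."""

    settings: ModelSettings = field(default_factory=ModelSettings)
    risk: RiskMappingParams = field(default_factory=RiskMappingParams)
    transitions: TransitionParameters = field(default_factory=TransitionParameters)
    weights: DisabilityWeights = field(default_factory=DisabilityWeights)
    costs: CostInputs = field(default_factory=CostInputs)
    scenarios: Mapping[str, ScenarioSpec] = field(default_factory=default_scenarios)

    def with_overrides(self, overrides: Mapping[str, float]) -> "ModelInputs":
        """Return a copy with dotted-path parameter overrides applied.

        Paths look like ``"costs.acute_mi_cost"``,
        ``"transitions.p_acute_mi_death"``, ``"weights.acute_stroke"`` or
        ``"scenarios.intervention_sustainment.ppy_saia_cost"``.
        """
        # group changes per block so interdependent fields (e.g. a weight
        # and its interval) are validated together
        by_block: dict[str, dict[str, object]] = {}
        by_scenario: dict[str, dict[str, object]] = {}
        for path, value in overrides.items():
            parts = path.split(".")
            if parts[0] == "scenarios":
                if len(parts) != 3 or parts[1] not in self.scenarios:
                    raise KeyError(f"unknown parameter path {path!r}")
                by_scenario.setdefault(parts[1], {})[parts[2]] = value
            elif len(parts) == 2 and parts[0] in {f.name for f in fields(self)}:
                block = getattr(self, parts[0])
                if not any(f.name == parts[1] for f in fields(block)):
                    raise KeyError(f"unknown parameter path {path!r}")
                by_block.setdefault(parts[0], {})[parts[1]] = value
            else:
                raise KeyError(f"unknown parameter path {path!r}")
        out = self
        for block_name, changes in by_block.items():
            out = replace(out, **{block_name: replace(getattr(out, block_name), **changes)})
        if by_scenario:
            scenarios = dict(out.scenarios)
            for name, changes in by_scenario.items():
                scenarios[name] = replace(scenarios[name], **changes)
            out = replace(out, scenarios=scenarios)
        return out
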