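"""10-year cardiovascular risk: chart lookup and risk arithmetic.

Baseline 10-year CVD risk comes from a non-laboratory risk chart — a
lookup table keyed by sex x age band x smoking x systolic-BP band x BMI
band, with half-open [low, high) bands. The engine converts 10-year risk
to a monthly first-event probability under a constant-hazard assumption,
maps sustained systolic-BP changes to relative risk (0.90 per 5 mmHg,
multiplicative), and combines within-arm risk reductions into the
cross-arm relative risk reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import DomainError, ModelSettings, RiskMappingParams

CHART_COLUMNS = [
    "sex", "age_lo", "age_hi", "smoker",
    "sbp_lo", "sbp_hi", "bmi_lo", "bmi_hi", "risk10",
]


class CoverageError(LookupError):
    """A patient attribute falls outside every chart band or life-table row."""


@dataclass(frozen=True)
class ChartParams:
    """Parametric (logistic) surface generating a synthetic risk chart.

    Cell risk is ``expit(intercept + slopes . centred covariates)``
    evaluated at band midpoints, so risk is monotone in any band whose
    slope is positive. The intercept is the calibration handle used to
    match a target event magnitude.
    """

    intercept: float = -2.45
    b_age: float = 0.06        # per year, centred at 50
    b_male: float = 0.30
    b_sbp: float = 0.025       # per mmHg, centred at 140
    b_bmi: float = 0.02        # per kg/m^2, centred at 25
    b_smoker: float = 0.50
    age_edges: tuple[float, ...] = tuple(float(a) for a in range(15, 100, 5))
    sbp_edges: tuple[float, ...] = tuple(float(s) for s in range(80, 260, 20))
    bmi_edges: tuple[float, ...] = tuple(float(b) for b in range(10, 60, 5))

    def __post_init__(self) -> None:
        for name in ("age_edges", "sbp_edges", "bmi_edges"):
            edges = getattr(self, name)
            if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
                raise DomainError(f"{name} must be strictly increasing with >= 2 edges")


class RiskChart:
    """Dense risk-chart lookup over (sex, age, smoker, SBP, BMI) bands."""

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in CHART_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"risk chart table missing columns: {missing}")
        if ((table["risk10"] < 0) | (table["risk10"] > 1)).any():
            raise DomainError("risk chart contains risks outside [0, 1]")
        self.table = table.reset_index(drop=True)
        self.age_edges = self._edges(table, "age")
        self.sbp_edges = self._edges(table, "sbp")
        self.bmi_edges = self._edges(table, "bmi")
        # dense array [sex(F=0,M=1), age band, smoker, sbp band, bmi band]
        shape = (
            2, len(self.age_edges) - 1, 2,
            len(self.sbp_edges) - 1, len(self.bmi_edges) - 1,
        )
        self._dense = np.full(shape, np.nan)
        si = (table["sex"].astype(str).str.upper() == "M").to_numpy().astype(int)
        ai = np.searchsorted(self.age_edges, table["age_lo"].to_numpy(), side="right") - 1
        ki = table["smoker"].astype(int).to_numpy()
        pi = np.searchsorted(self.sbp_edges, table["sbp_lo"].to_numpy(), side="right") - 1
        bi = np.searchsorted(self.bmi_edges, table["bmi_lo"].to_numpy(), side="right") - 1
        self._dense[si, ai, ki, pi, bi] = table["risk10"].to_numpy()
        if np.isnan(self._dense).any():
            raise ValueError("risk chart table does not cover the full band grid")

    @staticmethod
    def _edges(table: pd.DataFrame, stem: str) -> np.ndarray:
        lo = np.sort(table[f"{stem}_lo"].unique())
        hi = np.sort(table[f"{stem}_hi"].unique())
        return np.append(lo, hi[-1])

    @classmethod
    def from_logistic(cls, params: ChartParams) -> "RiskChart":
        """Build a chart from the logistic surface at band midpoints."""
        from scipy.special import expit

        rows = []
        ages = np.asarray(params.age_edges)
        sbps = np.asarray(params.sbp_edges)
        bmis = np.asarray(params.bmi_edges)
        for sex, male in (("F", 0.0), ("M", 1.0)):
            for a_lo, a_hi in zip(ages[:-1], ages[1:]):
                for smoker in (0, 1):
                    for p_lo, p_hi in zip(sbps[:-1], sbps[1:]):
                        for b_lo, b_hi in zip(bmis[:-1], bmis[1:]):
                            score = (
                                params.intercept
                                + params.b_age * ((a_lo + a_hi) / 2 - 50.0)
                                + params.b_male * male
                                + params.b_sbp * ((p_lo + p_hi) / 2 - 140.0)
                                + params.b_bmi * ((b_lo + b_hi) / 2 - 25.0)
                                + params.b_smoker * smoker
                            )
                            rows.append(
                                (sex, a_lo, a_hi, smoker, p_lo, p_hi, b_lo, b_hi,
                                 float(expit(score)))
                            )
        return cls(pd.DataFrame(rows, columns=CHART_COLUMNS))

    def _band_index(self, edges: np.ndarray, values: np.ndarray, what: str) -> np.ndarray:
        idx = np.searchsorted(edges, values, side="right") - 1
        bad = (idx < 0) | (idx >= len(edges) - 1)
        if bad.any():
            raise CoverageError(
                f"{what} value {np.asarray(values)[bad][0]!r} outside chart "
                f"coverage [{edges[0]}, {edges[-1]})"
            )
        return idx

    def lookup(self, sex, age, smoker, sbp, bmi):
        """Vectorised half-open band lookup; scalar in -> scalar out."""
        scalar = np.isscalar(age)
        sex = np.atleast_1d(np.asarray(sex, dtype=object))
        si = np.array([1 if str(s).upper().startswith("M") else 0 for s in sex])
        ai = self._band_index(self.age_edges, np.atleast_1d(age).astype(float), "age")
        pi = self._band_index(self.sbp_edges, np.atleast_1d(sbp).astype(float), "sbp")
        bi = self._band_index(self.bmi_edges, np.atleast_1d(bmi).astype(float), "bmi")
        ki = np.atleast_1d(smoker).astype(int)
        out = self._dense[si, ai, ki, pi, bi]
        return float(out[0]) if scalar else out

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RiskChart":
        return cls(pd.read_csv(path))


def lookup_risk(patient, chart: RiskChart) -> float:
    """Baseline 10-year CVD risk for one patient (mapping or namespace
    with age/sex/smoker/sbp/bmi attributes, e.g. a DataFrame row)."""
    get = patient.get if hasattr(patient, "get") else lambda k: getattr(patient, k)
    return chart.lookup(get("sex"), get("age"), get("smoker"), get("sbp"), get("bmi"))


def sbp_to_relative_risk(delta_sbp: float, params: RiskMappingParams | None = None) -> float:
    """Relative risk multiplier for a sustained systolic-BP reduction of
    ``delta_sbp`` mmHg: ``rr_per_step ** (delta_sbp / step_mmhg)``.

    Multiplicative across steps; negative deltas (BP increases) give
    multipliers above 1.
    """
    params = params or RiskMappingParams()
    return float(params.rr_per_step ** (delta_sbp / params.step_mmhg))


def relative_risk_reduction(a: float, b: float) -> float:
    """Cross-arm relative risk reduction from within-arm reductions:
    ``1 - (1 - B) / (1 - A)``.

    A is the comparator arm's within-arm 10-year risk reduction, B the
    intervention arm's; the result isolates the incremental effect of the
    implementation strategy.
    """
    if a >= 1.0:
        raise ZeroDivisionError("comparator risk reduction A must be < 1")
    return 1.0 - (1.0 - b) / (1.0 - a)


def risk_to_cycle_prob(risk10: float, settings: ModelSettings | None = None) -> float:
    """Monthly first-event probability from a 10-year risk under a
    constant hazard: ``1 - (1 - risk10)^(1/horizon)``."""
    settings = settings or ModelSettings()
    risk10 = np.asarray(risk10, dtype=float)
    if np.any((risk10 < 0) | (risk10 > 1)):
        raise DomainError("risk10 must be in [0, 1]")
    out = 1.0 - (1.0 - risk10) ** (1.0 / settings.horizon_cycles)
    return float(out) if out.ndim == 0 else out


def scenario_risk(risk10, reduction: float):
    """Scenario-adjusted 10-year risk: ``risk10 * (1 - reduction)``,
    clipped to [0, 1]. Reductions are applied on the 10-year risk scale
    before any per-cycle conversion."""
    if reduction >= 1.0:
        raise DomainError("risk reduction must be < 1")
    out = np.clip(np.asarray(risk10, dtype=float) * (1.0 - reduction), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out
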