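"""Discounted DALYs from trajectories: YLL via a life table, YLD via
disability weights.

Each death contributes the discounted value of the decedent's residual
life expectancy: a discount factor to the death cycle times a
continuous-time annuity over L years, ``(1 - (1+r)^-L) / ln(1+r)`` —
the standard discounted-YLL form. All-cause deaths accrue YLL (background
deaths included), so scenario DALY totals are all-cause totals. YLD
accrues per person-month of morbid-state occupancy at annual disability
weight / 12, discounted to the cycle; acute weights apply for the single
tunnel month, chronic weights for every occupied month.

Ages advance monthly from baseline; life-table lookup uses age at death
rounded down to whole years. No age-weighting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import DEATH_CAUSES, HealthState, Trajectory
from .params import DisabilityWeights, DomainError, ModelSettings
from .risk import CoverageError

LIFE_TABLE_COLUMNS = ["sex", "age", "residual_le_years"]


class LifeTable:
    """(sex, integer age) -> residual life expectancy in years."""

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in LIFE_TABLE_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"life table missing columns: {missing}")
        if (table["residual_le_years"] <= 0).any():
            raise DomainError("residual life expectancy must be strictly positive")
        self.table = table.reset_index(drop=True)
        self._by_sex: dict[str, np.ndarray] = {}
        self._max_age: dict[str, int] = {}
        for sex, grp in table.groupby("sex"):
            grp = grp.sort_values("age")
            ages = grp["age"].to_numpy(dtype=int)
            if not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)) or ages[0] != 0:
                raise ValueError("life table ages must be consecutive integers from 0")
            le = grp["residual_le_years"].to_numpy(dtype=float)
            if np.any(np.diff(le) > 0):
                raise DomainError("residual life expectancy must be non-increasing in age")
            self._by_sex[str(sex).upper()] = le
            self._max_age[str(sex).upper()] = int(ages[-1])

    def residual_le(self, sex, age):
        """Residual life expectancy; vectorised over equal-length inputs.
        Ages are floored to whole years for lookup."""
        sex_arr = np.atleast_1d(np.asarray(sex, dtype=object))
        age_arr = np.atleast_1d(np.asarray(age, dtype=float))
        idx = np.floor(age_arr).astype(int)
        out = np.empty(len(age_arr))
        is_male = np.array([str(s).upper().startswith("M") for s in sex_arr])
        for key, rows in (("F", ~is_male), ("M", is_male)):
            if not rows.any():
                continue
            if key not in self._by_sex:
                raise CoverageError(f"life table has no rows for sex {key!r}")
            bad = (idx[rows] < 0) | (idx[rows] > self._max_age[key])
            if bad.any():
                raise CoverageError(
                    f"life table does not cover age {age_arr[rows][bad][0]!r} "
                    f"for sex {key!r}"
                )
            out[rows] = self._by_sex[key][idx[rows]]
        return float(out[0]) if np.isscalar(age) else out

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path))


def discount_factor(t, settings: ModelSettings | None = None):
    """Discount multiplier for month index ``t``: ``(1+r)^(-t/12)``."""
    settings = settings or ModelSettings()
    t = np.asarray(t, dtype=float)
    out = (1.0 + settings.annual_discount) ** (-t / settings.cycles_per_year)
    return float(out) if out.ndim == 0 else out


def _annuity(le_years, rate: float):
    """Discounted value of a 1/year stream over ``le_years`` years,
    continuous-annuity form; equals ``le_years`` when rate is 0."""
    le = np.asarray(le_years, dtype=float)
    if rate == 0.0:
        return le
    return (1.0 - (1.0 + rate) ** (-le)) / np.log1p(rate)


def compute_yll(
    trajectory: Trajectory,
    life_table: LifeTable,
    settings: ModelSettings | None = None,
    causes: tuple[str, ...] = DEATH_CAUSES,
) -> float:
    """Discounted years of life lost over all deaths in the trajectory."""
    settings = settings or ModelSettings()
    T = trajectory.horizon
    cause_idx = [DEATH_CAUSES.index(c) for c in causes]
    d = trajectory.deaths[:, :, cause_idx].sum(axis=2)  # (S, T+1)
    cycles = np.arange(T + 1)
    df = discount_factor(cycles, settings)
    # (S, T+1) age-at-death matrix, floored to whole years for lookup
    ages_at_death = np.floor(
        trajectory.ages[:, None] + cycles[None, :] / settings.cycles_per_year
    ).astype(int)
    le = np.empty_like(ages_at_death, dtype=float)
    is_male = np.array([str(s).upper().startswith("M") for s in trajectory.sexes])
    for key, rows in (("F", ~is_male), ("M", is_male)):
        if rows.any():
            le[rows] = life_table.residual_le(
                np.repeat(key, rows.sum() * (T + 1)), ages_at_death[rows].ravel()
            ).reshape(-1, T + 1)
    return float(np.sum(d * df[None, :] * _annuity(le, settings.annual_discount)))


def compute_yld(
    trajectory: Trajectory,
    weights: DisabilityWeights,
    settings: ModelSettings | None = None,
) -> float:
    """Discounted years lived with disability.

    Chronic states accrue over lived months 0..T-1 (start-of-cycle
    occupancy); acute tunnel months appear in occupancy indices 1..T and
    accrue there, so events incident in the final cycle still count their
    one acute month.
    """
    settings = settings or ModelSettings()
    T = trajectory.horizon
    occ = trajectory.occupancy.sum(axis=0)  # (T+1, 8)
    df = discount_factor(np.arange(T + 1), settings)
    per_year = 1.0 / settings.cycles_per_year
    acute = (
        occ[1:, HealthState.ACUTE_MI] @ df[1:] * weights.acute_mi
        + occ[1:, HealthState.ACUTE_STROKE] @ df[1:] * weights.acute_stroke
    )
    chronic = (
        occ[:T, HealthState.CHRONIC_IHD] @ df[:T] * weights.chronic_ihd
        + occ[:T, HealthState.POST_STROKE] @ df[:T] * weights.post_stroke
    )
    return float((acute + chronic) * per_year)


@dataclass(frozen=True)
class OutcomeSummary:
    """Per-scenario health outcomes, rescaled to the reporting population."""

    scenario: str
    yll: float
    yld: float
    events: dict[str, float]
    scale: float = 100_000.0

    def __post_init__(self) -> None:
        if self.yll < 0 or self.yld < 0:
            raise DomainError("YLL and YLD must be non-negative")

    @property
    def dalys(self) -> float:
        return self.yll + self.yld


def compute_dalys(
    trajectory: Trajectory,
    life_table: LifeTable,
    weights: DisabilityWeights,
    settings: ModelSettings | None = None,
    scenario: str = "",
) -> OutcomeSummary:
    """Full discounted DALY summary (YLL + YLD) for one trajectory."""
    from .engine import summarize_events

    settings = settings or ModelSettings()
    scale = settings.population_scale / trajectory.initial_size
    return OutcomeSummary(
        scenario=scenario,
        yll=compute_yll(trajectory, life_table, settings) * scale,
        yld=compute_yld(trajectory, weights, settings) * scale,
        events=summarize_events(trajectory, settings),
        scale=settings.population_scale,
    )
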