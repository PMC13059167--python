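"""Two-pathway state-transition engine over monthly cycles.

Eight health states: NoCVD, the two one-cycle acute tunnel states
(AcuteMI, AcuteStroke), the chronic post-event states (ChronicIHD,
PostStroke), and three absorbing dead states split by cause (MI pathway,
stroke pathway, other). Only the first major cardiovascular event is
modelled. Within a cycle the NoCVD row resolves background death first
and events among survivors; acute occupants face only the acute case
fatality; chronic rows resolve cause-specific death first, background
death among survivors.

Acute events incident in the final cycle are resolved by one extra
acute-only bookkeeping step at the horizon boundary, so every first event
has an outcome and the case-fatality identities (acute deaths =
case fatality x incident events) hold exactly in cohort mode.

The engine runs in two modes sharing one bookkeeping container:
deterministic expected-occupancy propagation (cohort mode) and a seeded
individual-level microsimulation. Trajectories are aggregated into
(baseline age, sex) strata so discounted years of life lost can be
computed from age at death without storing per-person paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .params import DomainError, ModelSettings, TransitionParameters
from .risk import risk_to_cycle_prob, scenario_risk


class HealthState(IntEnum):
    NO_CVD = 0
    ACUTE_MI = 1
    CHRONIC_IHD = 2
    ACUTE_STROKE = 3
    POST_STROKE = 4
    DEAD_CVD_MI = 5
    DEAD_CVD_STROKE = 6
    DEAD_OTHER = 7


N_STATES = len(HealthState)
ALIVE_STATES = [
    HealthState.NO_CVD, HealthState.ACUTE_MI, HealthState.CHRONIC_IHD,
    HealthState.ACUTE_STROKE, HealthState.POST_STROKE,
]
#: order of the cause axis in ``Trajectory.deaths``
DEATH_CAUSES = ("acute_mi", "chronic_ihd", "acute_stroke", "post_stroke", "background")


@dataclass
class Trajectory:
    """Stratified bookkeeping of one model run.

    Arrays are indexed ``[stratum, time, ...]`` where a stratum is a
    (baseline age, sex) group of patients. ``occupancy`` holds expected
    (cohort mode) or realised (microsimulation) person-counts at time
    indices 0..T, recorded before the terminal acute resolution so the
    tunnel identity "incident events in cycle t = acute occupancy at
    t + 1" is visible. ``deaths`` has T + 1 cycle slots; slot T holds the
    horizon-boundary resolution of acute occupants. ``final_occupancy``
    is the post-resolution distribution.
    """

    ages: np.ndarray          # (S,) baseline age, years
    sexes: np.ndarray         # (S,) 'F' / 'M'
    occupancy: np.ndarray     # (S, T+1, 8)
    deaths: np.ndarray        # (S, T+1, 5) flows by DEATH_CAUSES
    incident: np.ndarray      # (S, T, 2) new AcuteMI, AcuteStroke per cycle
    final_occupancy: np.ndarray  # (S, 8)
    horizon: int

    @property
    def initial_size(self) -> float:
        return float(self.occupancy[:, 0, :].sum())

    @property
    def incident_mi(self) -> float:
        return float(self.incident[:, :, 0].sum())

    @property
    def incident_stroke(self) -> float:
        return float(self.incident[:, :, 1].sum())

    def deaths_by_cause(self) -> dict[str, float]:
        totals = self.deaths.sum(axis=(0, 1))
        return dict(zip(DEATH_CAUSES, (float(x) for x in totals)))

    def alive_person_cycles(self, discounted_weights: np.ndarray | None = None) -> float:
        """Person-cycles lived (months), summing start-of-cycle alive
        occupancy over cycles 0..T-1, optionally discount-weighted."""
        alive = self.occupancy[:, : self.horizon, :][:, :, [int(s) for s in ALIVE_STATES]]
        per_cycle = alive.sum(axis=(0, 2))
        if discounted_weights is None:
            return float(per_cycle.sum())
        return float(per_cycle @ discounted_weights[: self.horizon])


def build_transition_matrix(
    p_event: float, params: TransitionParameters
) -> np.ndarray:
    """8x8 row-stochastic monthly transition matrix for one event
    probability. Rows sum to one by construction."""
    if not 0.0 <= p_event <= 1.0:
        raise DomainError(f"p_event must be in [0, 1], got {p_event!r}")
    p_bg = params.p_background_death
    m = np.zeros((N_STATES, N_STATES))
    surv = 1.0 - p_bg
    ev = surv * p_event
    m[HealthState.NO_CVD, HealthState.DEAD_OTHER] = p_bg
    m[HealthState.NO_CVD, HealthState.ACUTE_MI] = ev * params.p_mi_split
    m[HealthState.NO_CVD, HealthState.ACUTE_STROKE] = ev * params.p_stroke_split
    m[HealthState.NO_CVD, HealthState.NO_CVD] = surv - ev
    m[HealthState.ACUTE_MI, HealthState.DEAD_CVD_MI] = params.p_acute_mi_death
    m[HealthState.ACUTE_MI, HealthState.CHRONIC_IHD] = 1.0 - params.p_acute_mi_death
    m[HealthState.ACUTE_STROKE, HealthState.DEAD_CVD_STROKE] = params.p_acute_stroke_death
    m[HealthState.ACUTE_STROKE, HealthState.POST_STROKE] = 1.0 - params.p_acute_stroke_death
    for state, p_cause, dead in (
        (HealthState.CHRONIC_IHD, params.p_chronic_ihd_death, HealthState.DEAD_CVD_MI),
        (HealthState.POST_STROKE, params.p_post_stroke_death, HealthState.DEAD_CVD_STROKE),
    ):
        m[state, dead] = p_cause
        m[state, HealthState.DEAD_OTHER] = (1.0 - p_cause) * p_bg
        m[state, state] = (1.0 - p_cause) * (1.0 - p_bg)
    for dead in (HealthState.DEAD_CVD_MI, HealthState.DEAD_CVD_STROKE, HealthState.DEAD_OTHER):
        m[dead, dead] = 1.0
    return m


def _propagate(
    occ0: np.ndarray,
    p_event: np.ndarray,
    ages: np.ndarray,
    sexes: np.ndarray,
    params: TransitionParameters,
    settings: ModelSettings,
) -> Trajectory:
    """Deterministic expected-occupancy propagation; ``occ0`` is
    (S, 8) and ``p_event`` per stratum."""
    T = settings.horizon_cycles
    S = occ0.shape[0]
    occ = np.zeros((S, T + 1, N_STATES))
    deaths = np.zeros((S, T + 1, len(DEATH_CAUSES)))
    incident = np.zeros((S, T, 2))
    occ[:, 0, :] = occ0
    p_bg = params.p_background_death
    cur = occ0.copy()
    for t in range(T):
        no = cur[:, HealthState.NO_CVD]
        d_bg_no = no * p_bg
        ev = (no - d_bg_no) * p_event
        mi = ev * params.p_mi_split
        st = ev - mi
        ami = cur[:, HealthState.ACUTE_MI]
        d_ami = ami * params.p_acute_mi_death
        ihd = cur[:, HealthState.CHRONIC_IHD]
        d_ihd = ihd * params.p_chronic_ihd_death
        bg_ihd = (ihd - d_ihd) * p_bg
        ast = cur[:, HealthState.ACUTE_STROKE]
        d_ast = ast * params.p_acute_stroke_death
        ps = cur[:, HealthState.POST_STROKE]
        d_ps = ps * params.p_post_stroke_death
        bg_ps = (ps - d_ps) * p_bg
        nxt = np.zeros_like(cur)
        nxt[:, HealthState.NO_CVD] = no - d_bg_no - ev
        nxt[:, HealthState.ACUTE_MI] = mi
        nxt[:, HealthState.CHRONIC_IHD] = (ami - d_ami) + (ihd - d_ihd - bg_ihd)
        nxt[:, HealthState.ACUTE_STROKE] = st
        nxt[:, HealthState.POST_STROKE] = (ast - d_ast) + (ps - d_ps - bg_ps)
        nxt[:, HealthState.DEAD_CVD_MI] = cur[:, HealthState.DEAD_CVD_MI] + d_ami + d_ihd
        nxt[:, HealthState.DEAD_CVD_STROKE] = cur[:, HealthState.DEAD_CVD_STROKE] + d_ast + d_ps
        nxt[:, HealthState.DEAD_OTHER] = cur[:, HealthState.DEAD_OTHER] + d_bg_no + bg_ihd + bg_ps
        deaths[:, t, 0] = d_ami
        deaths[:, t, 1] = d_ihd
        deaths[:, t, 2] = d_ast
        deaths[:, t, 3] = d_ps
        deaths[:, t, 4] = d_bg_no + bg_ihd + bg_ps
        incident[:, t, 0] = mi
        incident[:, t, 1] = st
        occ[:, t + 1, :] = nxt
        cur = nxt
    # horizon-boundary resolution of the last tunnel cohort
    final = cur.copy()
    d_ami = final[:, HealthState.ACUTE_MI] * params.p_acute_mi_death
    d_ast = final[:, HealthState.ACUTE_STROKE] * params.p_acute_stroke_death
    deaths[:, T, 0] = d_ami
    deaths[:, T, 2] = d_ast
    final[:, HealthState.CHRONIC_IHD] += final[:, HealthState.ACUTE_MI] - d_ami
    final[:, HealthState.POST_STROKE] += final[:, HealthState.ACUTE_STROKE] - d_ast
    final[:, HealthState.DEAD_CVD_MI] += d_ami
    final[:, HealthState.DEAD_CVD_STROKE] += d_ast
    final[:, HealthState.ACUTE_MI] = 0.0
    final[:, HealthState.ACUTE_STROKE] = 0.0
    return Trajectory(
        ages=np.asarray(ages, dtype=float),
        sexes=np.asarray(sexes, dtype=object),
        occupancy=occ,
        deaths=deaths,
        incident=incident,
        final_occupancy=final,
        horizon=T,
    )


def run_cohort(
    initial_size: float,
    p_event: float,
    params: TransitionParameters,
    settings: ModelSettings,
    age: float = 50.0,
    sex: str = "F",
) -> Trajectory:
    """Homogeneous deterministic cohort run: everyone starts in NoCVD
    with the same monthly event probability."""
    occ0 = np.zeros((1, N_STATES))
    occ0[0, HealthState.NO_CVD] = float(initial_size)
    return _propagate(
        occ0, np.array([p_event]), np.array([age]), np.array([sex], dtype=object),
        params, settings,
    )


def run_cohort_from_patients(
    cohort: pd.DataFrame,
    params: TransitionParameters,
    settings: ModelSettings,
    risk_reduction: float = 0.0,
) -> Trajectory:
    """Deterministic propagation of a heterogeneous patient table.

    Each patient contributes one unit of occupancy with a monthly event
    probability derived from their own scenario-adjusted 10-year risk.
    The result keeps one stratum per patient row so age-at-death
    bookkeeping stays exact.
    """
    _require_risk(cohort)
    risks = scenario_risk(cohort["risk10"].to_numpy(), risk_reduction)
    p_event = risk_to_cycle_prob(risks, settings)
    n = len(cohort)
    occ0 = np.zeros((n, N_STATES))
    occ0[:, HealthState.NO_CVD] = 1.0
    return _propagate(
        occ0, np.atleast_1d(p_event),
        cohort["age"].to_numpy(dtype=float),
        cohort["sex"].to_numpy(dtype=object),
        params, settings,
    )


def _require_risk(cohort: pd.DataFrame) -> None:
    if "risk10" not in cohort.columns or cohort["risk10"].isna().any():
        raise ValueError("every patient must have risk10 set")


def run_microsim(
    cohort: pd.DataFrame,
    params: TransitionParameters,
    settings: ModelSettings,
    seed: int | np.random.Generator,
    risk_reduction: float = 0.0,
    return_paths: bool = False,
):
    """Seeded individual-level simulation of the same state process.

    Uniform draws are consumed in a fixed (patient, cycle, slot) layout
    regardless of state, so two runs from the same seed but different
    event probabilities use common random numbers: lowering a patient's
    risk can only remove or delay events, never create them. Returns a
    stratified :class:`Trajectory` (grouped by baseline age and sex);
    with ``return_paths=True`` also the (n, T+1) state-path array.
    """
    _require_risk(cohort)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    risks = scenario_risk(cohort["risk10"].to_numpy(), risk_reduction)
    p_event = np.atleast_1d(risk_to_cycle_prob(risks, settings))
    T = settings.horizon_cycles
    n = len(cohort)
    ages_all = cohort["age"].to_numpy(dtype=float)
    sexes_all = cohort["sex"].to_numpy(dtype=object)

    strata_keys = pd.MultiIndex.from_arrays([ages_all, sexes_all])
    uniq, stratum = np.unique(strata_keys.to_numpy(), return_inverse=True)
    S = len(uniq)
    ages = np.array([k[0] for k in uniq], dtype=float)
    sexes = np.array([k[1] for k in uniq], dtype=object)

    occ = np.zeros((S, T + 1, N_STATES))
    deaths = np.zeros((S, T + 1, len(DEATH_CAUSES)))
    incident = np.zeros((S, T, 2))
    state = np.full(n, int(HealthState.NO_CVD), dtype=np.int8)
    paths = np.zeros((n, T + 1), dtype=np.int8) if return_paths else None

    def record_occupancy(t: int) -> None:
        np.add.at(occ, (stratum, t, state.astype(int)), 1.0)

    record_occupancy(0)
    p_bg = params.p_background_death
    for t in range(T):
        u = rng.random((n, 3))
        new = state.copy()
        no = state == HealthState.NO_CVD
        die_bg = no & (u[:, 0] < p_bg)
        ev = no & ~die_bg & (u[:, 1] < p_event)
        ev_mi = ev & (u[:, 2] < params.p_mi_split)
        ev_st = ev & ~ev_mi
        new[die_bg] = HealthState.DEAD_OTHER
        new[ev_mi] = HealthState.ACUTE_MI
        new[ev_st] = HealthState.ACUTE_STROKE

        ami = state == HealthState.ACUTE_MI
        d_ami = ami & (u[:, 0] < params.p_acute_mi_death)
        new[ami] = HealthState.CHRONIC_IHD
        new[d_ami] = HealthState.DEAD_CVD_MI

        ihd = state == HealthState.CHRONIC_IHD
        d_ihd = ihd & (u[:, 0] < params.p_chronic_ihd_death)
        bg_ihd = ihd & ~d_ihd & (u[:, 1] < p_bg)
        new[d_ihd] = HealthState.DEAD_CVD_MI
        new[bg_ihd] = HealthState.DEAD_OTHER

        ast = state == HealthState.ACUTE_STROKE
        d_ast = ast & (u[:, 0] < params.p_acute_stroke_death)
        new[ast] = HealthState.POST_STROKE
        new[d_ast] = HealthState.DEAD_CVD_STROKE

        ps = state == HealthState.POST_STROKE
        d_ps = ps & (u[:, 0] < params.p_post_stroke_death)
        bg_ps = ps & ~d_ps & (u[:, 1] < p_bg)
        new[d_ps] = HealthState.DEAD_CVD_STROKE
        new[bg_ps] = HealthState.DEAD_OTHER

        for cause_idx, mask in (
            (0, d_ami), (1, d_ihd), (2, d_ast), (3, d_ps),
            (4, die_bg | bg_ihd | bg_ps),
        ):
            np.add.at(deaths, (stratum[mask], t, cause_idx), 1.0)
        np.add.at(incident, (stratum[ev_mi], t, 0), 1.0)
        np.add.at(incident, (stratum[ev_st], t, 1), 1.0)
        state = new
        record_occupancy(t + 1)
        if paths is not None:
            paths[:, t + 1] = state
    # horizon-boundary resolution of acute occupants
    u = rng.random(n)
    final_state = state.copy()
    ami = state == HealthState.ACUTE_MI
    d_ami = ami & (u < params.p_acute_mi_death)
    final_state[ami] = HealthState.CHRONIC_IHD
    final_state[d_ami] = HealthState.DEAD_CVD_MI
    ast = state == HealthState.ACUTE_STROKE
    d_ast = ast & (u < params.p_acute_stroke_death)
    final_state[ast] = HealthState.POST_STROKE
    final_state[d_ast] = HealthState.DEAD_CVD_STROKE
    np.add.at(deaths, (stratum[d_ami], T, 0), 1.0)
    np.add.at(deaths, (stratum[d_ast], T, 2), 1.0)
    final = np.zeros((S, N_STATES))
    np.add.at(final, (stratum, final_state.astype(int)), 1.0)

    traj = Trajectory(
        ages=ages, sexes=sexes, occupancy=occ, deaths=deaths,
        incident=incident, final_occupancy=final, horizon=T,
    )
    return (traj, paths) if return_paths else traj


def summarize_events(trajectory: Trajectory, settings: ModelSettings | None = None) -> dict[str, float]:
    """Event and death counts rescaled to the reporting population
    (per 100,000 by default).

    ``mi_deaths`` / ``stroke_deaths`` are acute (tunnel-cycle) deaths —
    the counts that obey the case-fatality identities; chronic-state
    deaths are reported separately.
    """
    settings = settings or ModelSettings()
    scale = settings.population_scale / trajectory.initial_size
    d = trajectory.deaths_by_cause()
    return {
        "acute_mi": trajectory.incident_mi * scale,
        "acute_stroke": trajectory.incident_stroke * scale,
        "mi_deaths": d["acute_mi"] * scale,
        "stroke_deaths": d["acute_stroke"] * scale,
        "chronic_ihd_deaths": d["chronic_ihd"] * scale,
        "post_stroke_deaths": d["post_stroke"] * scale,
        "background_deaths": d["background"] * scale,
        "person_cycles_alive": trajectory.alive_person_cycles() * scale,
    }


def trajectory_to_long(trajectory: Trajectory) -> pd.DataFrame:
    """Long-format (cycle, state, count) occupancy table."""
    counts = trajectory.occupancy.sum(axis=0)
    T = trajectory.horizon
    return pd.DataFrame(
        {
            "cycle": np.repeat(np.arange(T + 1), N_STATES),
            "state": [s.name.lower() for _ in range(T + 1) for s in HealthState],
            "count": counts.ravel(),
        }
    )
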