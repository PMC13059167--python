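# Methods

## Model structure

The engine simulates two first-event cardiovascular pathways (ischemic
heart disease / myocardial infarction, and stroke) over 120 monthly
cycles. States: NoCVD → {AcuteMI, AcuteStroke} (one-cycle tunnels) →
{ChronicIHD, PostStroke} → cause-split absorbing death states
(MI-pathway CVD death, stroke-pathway CVD death, other). Only the first
major event is modelled; chronic-state occupants never generate new
events.

Within-cycle ordering is fixed and documented because it makes several
identities exact:

- **NoCVD row** — background death is resolved first; events occur among
  survivors with monthly probability $p$ and split 55/45 into MI/stroke.
- **Acute rows** — occupants face only the acute case fatality (0.65 MI,
  0.38 stroke); no background mortality that cycle. Survivors move to the
  chronic state.
- **Chronic rows** — cause-specific death first, background death among
  survivors, otherwise stay.
- **No half-cycle correction**: with monthly cycles the correction is
  negligible and the identities below stay exact.

**Horizon boundary.** Events incident in the final cycle enter the
tunnel at time index 120. They are resolved by one extra acute-only
bookkeeping step (no new events, no background or chronic deaths), so
every incident event has an outcome and, in cohort mode,

cumulative acute MI deaths = 0.65 × cumulative incident MI (exactly),

and likewise 0.38 for stroke. "MI deaths" and "stroke deaths" in
summaries are these acute tunnel deaths; chronic-state deaths are
reported separately (the published outcome table follows the same
convention — its printed death counts equal event counts times the acute
case fatalities).

**Risk handling.** Each patient's 10-year risk is evaluated once at
baseline from the risk chart and held fixed over the horizon (no annual
re-scoring as patients age); ages still advance monthly for
years-of-life-lost bookkeeping. Scenario effectiveness is applied as a
proportional reduction on the 10-year risk before the constant-hazard
conversion $p = 1-(1-R)^{1/120}$. Both conventions are deliberate,
documented simplifications; the constant-hazard conversion is standard
in state-transition cost-effectiveness analysis and exactly invertible,
which the tests exploit. Background transitions use the flat monthly
0.0018 probability; the life table is used only for YLL.

Two modes share the same bookkeeping container: deterministic
expected-occupancy propagation (cohort mode; all base-case results), and
a seeded individual-level microsimulation whose aggregate converges to
the cohort solution (verified across ≥20 seeds in the tests). The
microsimulation consumes uniform draws in a fixed (patient, cycle, slot)
layout regardless of state, so scenarios evaluated from the same seed
share common random numbers: reducing a patient's risk can only remove
or delay that patient's events. This makes within-draw scenario
contrasts noise-free in sign.

## Health outcomes

DALYs = YLL + YLD, both discounted at 3%/year with monthly factors
$(1+r)^{-t/12}$.

- **YLL**: every death (all causes, background included) contributes the
  discounted continuous annuity over residual life expectancy $L$ at age
  of death: discount-to-death × $(1-(1+r)^{-L})/\ln(1+r)$. Age at death
  is baseline age plus elapsed months, floored to whole years for the
  life-table lookup. All-cause accrual was chosen because the published
  total DALY magnitudes (≈265,000 per 100,000 over ten years) are far
  larger than CVD-only losses can produce; scenario contrasts then
  automatically net out the partial YLL reclaimed when an averted CVD
  death is replaced by a later background death.
- **YLD**: each person-month in a morbid state accrues annual weight/12
  (acute MI 0.439, chronic IHD 0.101, acute stroke 0.920, post-stroke
  0.266). Acute weights apply to the single tunnel month (including the
  boundary-resolved one); chronic accrual stops at the horizon. No
  age-weighting and no standardisation beyond discounting.

## Costing (2023 USD, health-system perspective)

- **Program delivery** per patient-year (2.46 / 7.07 / 7.86 by scenario)
  accrues pro-rated to alive person-months, discounted — mirroring how
  the rates were derived (expenditure ÷ observed patient-years). The
  $0.79 increment of intervention sustainment is carried as a separate
  system-strengthening component so the three-way cost decomposition
  (direct / facility-indirect / system-strengthening) is read off
  directly; the decomposition sums to the total by construction.
- **Medication**: $17.50/year × treatment coverage (2.1% baseline, 8.2%
  sustainment) per alive person-month. Coverage applies to all alive
  patients, matching how coverage was reported (% of participants
  accessing treatment).
- **CVD care** is gated by care access, which affects costs only, not
  survival (the case fatalities are unconditional): acute events incur
  the one-time cost × 20% access × 27% inpatient markup at the event
  month; chronic person-months incur annual cost/12 × chronic access
  (default also 20%, separately configurable) × 7.4% outpatient markup.
- The expenditure-ledger reader divides program-tagged category totals
  by patient-years; research-tagged lines are always excluded. The
  packaged example ledger is synthetic: constructed to reproduce the
  published per-patient-year totals, not a copy of the trial's cost
  tables.
- The status-quo scenario is a pure do-nothing reference (no program
  cost, no medication coverage, zero risk reduction); the actual ICER
  comparator is control-baseline, which carries the $2.46 standard-of-
  care cost.

## Synthetic data

No patient-level trial data are public, so the generator emulates the
study conditions rather than any real cohort:

- **Cohort** (n = 334 by default): age truncated-normal mean 45, sd 10
  on [30, 75]; 55% female; systolic BP normal (135, 18) truncated to
  [90, 220] mmHg; BMI (26, 4.5) on [15, 45]; smoking prevalence 12%.
  These are plausibility choices for adults in HIV care screened for
  hypertension; only the induced risk distribution, not the raw
  attributes, drives the model.
- **Risk chart**: a logistic surface in centred age, sex, SBP, BMI and
  smoking, evaluated at band midpoints (5-year age bands, 20 mmHg SBP
  bands, 5 kg/m² BMI bands, half-open [low, high)). Positive slopes make
  risk monotone in age and SBP by construction. The chart is a synthetic
  stand-in for the WHO non-laboratory charts, not a reproduction of
  them.
- **Calibration**: a monotone one-dimensional root find on the chart
  intercept drives the cohort's deterministic 10-year control-baseline
  run to a target cumulative first-event count — by default 7,980 per
  100,000, the published control-baseline MI + stroke total. Calibration
  targets total events, not per-cause counts, because the 55/45 split is
  applied downstream.
- **Life table**: residual life expectancy
  $e(x) = e_0 (1 - x/105)^{1.6}$ with $e_0 = 62$ years and a 4-year
  female–male gap, giving e(30) ≈ 36, e(45) ≈ 25, e(60) ≈ 16 — levels
  typical of Mozambique-like settings. Strictly decreasing and positive
  through age 104 (maximum attainable age plus margin).
- **Seeding**: one master seed; per-component child streams (cohort,
  PSA, microsimulation) are spawned deterministically from it.

What passing tests therefore show: the mechanics (identities,
conservation, discounting, calibration, dominance logic, CEAC
construction) are correct under realistic-magnitude inputs. What they do
not show: fidelity to the real trial cohort's attribute joint
distribution, to the actual WHO chart values, or to the actual
Mozambican life table.

## Sensitivity analysis

- **One-way DSA**: three full deterministic evaluations (base, low,
  high) per parameter; printed ranges are used where available
  (cost intervals, disability-weight intervals, care access 0–80%),
  otherwise ±20%.
- **PSA distributions**: costs — triangular over (min, central, max)
  with the printed central value treated as the mode; disability weights
  — beta with shapes moment-matched to the printed mean and an SD
  inferred as (upper95 − lower95)/3.92; transition probabilities —
  uniform ±20% clipped to [0, 1] (the source states only "plausible
  ranges"). Draws are joint and independent; no correlation structure is
  imposed.
- **PSA modes**: the implementation-strategy comparison uses the
  deterministic cohort engine per draw (pure parameter uncertainty);
  the intervention comparison can additionally use the hybrid mode — a
  334-patient microsimulation per scenario per draw with common random
  numbers (334 × 3 × 100 > 100,000 simulated paths) — to reflect
  patient-level heterogeneity. The split mirrors the published
  uncertainty pattern: a tight parameter-driven interval for the
  strategy ICER and a wide heterogeneity-driven interval for the
  intervention ICER.
- **CEAC**: probability cost-effective = fraction of draws with positive
  net monetary benefit (WTP × DALYs averted − incremental cost), which
  remains well-defined when increments change sign.

## Numerical conventions

- Occupancy is recorded at time indices 0..120; flow quantities (events,
  deaths) during month $t$ are discounted with factor $t$; occupancy-
  based accruals use start-of-month occupancy over months 0..119 (acute
  tunnel months, which appear at indices 1..120, accrue at their index).
- Conservation (occupancy sums to the initial cohort every cycle) holds
  to 1e-9; the algebraic identities (RRR composition, constant-hazard
  inversion, BP-mapping multiplicativity) are asserted to 1e-12.
- Monetary values are reported to 2 decimals and probabilities to 6
  significant figures in outputs; all internal computation is double
  precision.
- ICERs are computed only when both increments are positive (or both
  negative, the savings-per-DALY-lost trade-off); otherwise dominance or
  undefined flags are returned rather than exceptions.
- Problem sizes used by the shipped analyses: 334-patient cohorts,
  100-draw PSAs, 100,000-person reporting scale, and 2,000-patient ×
  20-seed microsimulation checks — sizes at which the deterministic
  results are exact and Monte-Carlo checks are stable.

## Known limitations and documented discrepancies

- The published outcome table is not internally consistent: its two
  scenario contrasts imply ≈10 and ≈18 DALYs averted per averted event
  respectively, and its printed intervention ICER ($212) cannot be
  recovered from its own rounded totals (which give ≈$151). An
  internally consistent engine cannot match all of these numbers at
  once. This package reports its own arithmetic: with events calibrated
  to the published baseline magnitude, the intervention ICER is ≈$240
  and the implementation-strategy ICER ≈$83 per DALY averted. Both
  comparisons' qualitative conclusions (far below the $647 threshold;
  the strategy's increment much cheaper per DALY than the intervention;
  the strategy cost-effective in 100% of PSA draws at $162.5) are
  reproduced.
- Similarly, the published total cost deltas between sustainment
  scenarios appear closer to undiscounted person-year arithmetic without
  event-cost offsets; this model discounts program costs to alive
  person-months and nets event-cost savings, yielding a somewhat smaller
  incremental cost.
- Recurrent events, hypertensive heart disease, treatment-dependent case
  fatality, societal/indirect costs, and QALYs are out of scope.
- Whether care access should modify acute survival (not only costs) is
  an open interpretive question; cost-only was chosen because the
  printed case fatalities are unconditional.
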