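# Methods

## Model structure

`cystcea` is a deterministic Markov cohort model with three health states
for a patient under surveillance for an asymptomatic pancreatic cystic
neoplasm: **asymptomatic**, **symptomatic**, **dead** (absorbing). The
cohort (default 1000 patients, base age 60) is propagated for `n_cycles`
1-year cycles (default 10); transitions happen at cycle end, so the
occupancy used for cycle *t*'s costs and utilities is the start-of-cycle
vector.

Per-cycle transition probabilities at age *a*:

- asymptomatic → dead: qx(a), the life-table annual death probability,
  plus the EUS-FNA procedural mortality (10⁻⁴) in cycles whose calendar
  contains an EUS;
- asymptomatic → symptomatic: p_sym · (1 − qx(a)) with p_sym = 0.02.
  Competing risks combine multiplicatively so rows stay stochastic for
  any parameter values;
- symptomatic → dead: 1 − (1 − qx)·(1 − p_excess), where p_excess =
  0.6 · (malignant fraction among the symptomatic). The modelled
  population has no risk of malignant progression, so p_excess is 0 in
  the base case; it activates only with `include_malignant_branch`.

The diagnostic-accuracy parameters (correct-diagnosis probability 0.85,
per-modality sensitivity/specificity ranges) are stored and sampled in
PSA, but enter the state dynamics only through the optional
`include_misdiagnosis` pathway (default off): the mechanics by which
imaging accuracy alters effectiveness are not specified by the source
analysis, and the base-case cost arithmetic reproduces without them.

## Cycle length and the effectiveness scale

The source analysis is internally inconsistent about its time axis (a
"cycle set to 10 years" alongside "10 cycles" and a "10-year horizon"),
and its published QALYs (up to 13.57) exceed any possible 10 × 0.80
ceiling, so its exact calibration cannot be recovered from the text.
This package fixes 1-year cycles over a 10-year horizon. Consequently
*simulated* absolute QALYs (≈ 7.1 for annual CEUS surveillance at base
age 60) are on the model's own scale and are reported separately
(`model_outcomes.csv`); all table-reproduction arithmetic (NHB, savings,
means, dominance) takes the published (cost, QALY) pairs as inputs, where
the reproduction is exact.

## Strategies and calendar provenance

Exam calendars carry explicit provenance:

- `derived_from_text` — the CEUS-strategy calendars, stated verbatim:
  annual CEUS (< 1 cm and SCN); 4-3-3-3-3 then annual CEUS (1–2 cm);
  2 MRI then 9 × (2 CEUS + 1 MRI) (2–3 cm); 4 MRI then 9 × (3 CEUS +
  1 MRI) (MCN 3–4 cm).
- `calibrated_to_published_costs` — the Fukuoka calendars. Their verbal
  descriptions are ambiguous about baseline exams and the CT-vs-MRI
  choice, but the published totals decompose uniquely over the unit
  costs: 1537.27 € = 7 MRI, 1756.88 € = 8 MRI, 8268.44 € = 10 EUS +
  4 MRI. The exams are spread as evenly as the described intervals
  allow, and a test pins each calendar to its total to the cent.

The Italian and European/ACG comparators admit no such decomposition
(828.22 €, 1663.95 €, 4392.20 €, 8847.10 €, 2196.10 €, 1662.40 € have no
small integer representation over the four unit costs, and parts of those
pathways use plain ultrasound, which has no listed cost). They are
represented as **fixed-cost strategies** whose (cost, QALY) pairs come
from the bundled published table (`cystcea.reference`) — honest
provenance instead of invented calendars.

Two published numbers are carried without being resolved: the 2–3 cm CEUS
calendar sums to 3684.71 € while the published table prints 2751.99 € for
that row (and 3684.71 € for MCN 3–4 cm, whose calendar sums to
4758.43 €); a row mix-up or an expectation-weighted cost is possible.
The schedule-derived costs are exposed via `schedule_cost`, the published
values via the reference table; they are never silently blended.

## Costs, utilities, discounting

All of a cycle's exams are booked at cycle start for the fraction of the
cohort then alive; with the default discount rate of 0 this reproduces
the published undiscounted arithmetic (705 € = 10 × 70.50 €). A
configurable discount rate applies the factor (1 + r)^−(t−1) to both
streams; the usual 3–3.5 % practice is available but off by default
because the published totals are undiscounted.

Utilities: asymptomatic patients under non-invasive surveillance start at
0.78 (0.73 in cycles containing an EUS), decline by 0.01 per year of
ageing, and drop by a further 0.03 while symptomatic; the dead contribute
0. Utilities are clamped at 0 (with a logged warning) if decrements ever
exceed the base value. No half-cycle correction is applied by default
(none is described); `half_cycle_correction` averages start- and
end-of-cycle occupancy when set.

## Rendering convention

The published tables truncate toward zero at the printed precision
(12.4888 → 12.48, 13.5465 → 13.54): `cystcea.truncate` reproduces this,
and the report renderer applies it; CSVs keep full double precision. Two
published values do not follow any consistent convention and are *not*
reproduced: the cross-scenario mean of the published per-scenario ratios
is 181.986 (printed 181.99 in one place and 181.93 in another — the
rounded form is reported), and two savings cells (12.22 and 321) conflict
with their own table's costs (arithmetic: 123.22 and 360.96, the values
this package computes). The printed per-scenario "ICER" column is close
to, but not exactly, cost/effectiveness (e.g. 126.70 printed vs 127.74
computed for 1480.5/11.59); the package computes the exact ACER and
stores the printed value separately as `icer_printed`.

## Probabilistic sensitivity analysis

Second-order distributions follow the stated families: **gamma** for
costs, parameterized shape k = 1/cv², scale θ = mean·cv² so the mean is
preserved exactly; **normal** for probabilities, proportions and
utilities, truncated to [0, 1] by rejection (counts logged); **uniform**
for sensitivity/specificity over their published ranges. The spreads are
not reported by the source; the defaults — cv 0.20 for costs, sd 10 % of
the value for probability-scale parameters — are this package's choice
and are configurable. Complement pairs (CIS/invasive split,
head-neck/body-tail location) are drawn jointly so sum-to-one invariants
hold by construction. Each parameter draws from its own named stream
keyed by (seed, parameter name), so adding a parameter never perturbs
another's draws and regression tests stay stable.

Per draw, schedule-backed strategies (CEUS, Fukuoka) re-run the full
pipeline: drawn unit costs × fixed exam counts, drawn transition and
utility parameters through the Markov engine. Fixed-cost comparators draw
cost ~ gamma around their published total, and effectiveness ~ normal
around the published QALY **rescaled into the model's effectiveness
scale** by the ratio (simulated base-case CEUS QALY)/(published CEUS
QALY). This keeps all strategies on one effectiveness scale, preserving
the published ordering in expectation, which is what makes acceptability
curves across mixed-provenance strategies meaningful.

CEAC: at each willingness-to-pay λ on the grid (default 0–60 k€ in 5 k€
steps), the probability a strategy is optimal is the fraction of draws in
which it attains the maximal NMB = λ·E − C, ties splitting mass equally —
probabilities therefore sum to exactly 1. "Within budget" is ambiguous in
the source; the headline definition here is the fraction of draws with
ACER ≤ λ at λ = 30 000 €/QALY, with the alternative NMB > 0 fraction
reported alongside.

The source's PSA percentages (45 %, 56 %, … within budget / optimal) are
**not** reproduction targets: they depend on unreported spreads and draw
counts. What is asserted is the qualitative ordering — CEUS ≥ Italian ≥
Fukuoka probability-optimal at 30 k€ in the < 1 cm scenario — as a
stochastic smoke test; because the CEUS-vs-Italian net-benefit gap
(≈ 0.1 QALY) is small relative to the draw noise, the test uses 1500
draws so the ordering estimate is stable across seeds.

Tornado analysis varies one parameter at a time over stated ranges
(defaults: costs ± 20 %, probabilities/utilities ± 10 % clipped to
[0, 1]) and recomputes NHB through the full pipeline; it is defined for
schedule-backed strategies only, since a fixed-cost comparator's NHB is
not a function of the parameter set. Entries sort by descending bar
width, ties alphabetical.

## Synthetic data

No mortality table accompanies the analysis, so a **Gompertz–Makeham**
stand-in is bundled: hazard μ(a) = λ + α·e^(βa) with λ = 5·10⁻⁴,
α = 2·10⁻⁵, β = 0.095 per year, giving qx(60) ≈ 0.0065 and qx(70) ≈
0.016 — in the range of recent Western-European all-cause mortality. The
table is monotone in age, closed out at qx = 1 at the top age, and any
user-supplied (age, qx) CSV is accepted in its place. Synthetic cohorts
fix age at 60 (the base case), draw sex at the stated female ratios
(BD-IPMN 1:1, MCN 9:1, SCN 4:1) and flag 15 % of BD-IPMN patients as
harbouring a malignant branch lesion. The generator emulates the *inputs*
the model consumes, not patient-level disease trajectories: passing tests
demonstrate the arithmetic and engine are correct under the stated
conditions, not that the surveillance conclusions transfer to any real
registry population.

## Problem sizes

The default test and acceptance runs use 1000 random matrix instances for
the engine-vs-closed-form check, 100 000 draws for the gamma moment
check, and 1500 PSA draws per scenario for acceptability curves; the
full deterministic pipeline evaluates in well under a millisecond per
draw, so these sizes are comfortable on a laptop.

## Known limitations

- Absolute simulated QALYs are calibration-dependent (see above); only
  published-value arithmetic is treated as exactly reproducible.
- Misdiagnosis and the malignant-branch pathway are structural stubs
  (default off) because their mechanics are unspecified in the source.
- No microsimulation, tunnel states, or post-detection treatment
  pathways; EVPI is not computed.
- Comparator strategies are fixed-cost: their uncertainty in PSA is
  parametric around published totals, not mechanistic.
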