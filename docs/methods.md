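# Methods

This note documents the model implemented in `lipidcea`: its structure
and assumptions, the synthetic input generator, the parameters that
matter, the numerical choices, and what the package's tests do and do
not demonstrate about real data.

## Decision problem

For a population with established atherosclerotic CVD on background
statin therapy, compare every lipid treatment-escalation threshold on a
grid (LDL-C 0–4.0 mmol/L, non-HDL-C 0.5–4.5 mmol/L, step 0.1) by
lifetime discounted cost and QALYs, from the perspective of the health
and social care payer. Escalation is sequential — ezetimibe first, then
an injectable (inclisiran or a PCSK9 inhibitor) — and is triggered by a
single annual lipid measurement above the threshold. The model also has
target-like behaviour: if the cheaper drug alone brings the measured
level just below the threshold, the more expensive drug is not added.

## Cohort structure

Each sex's baseline LDL-C distribution is a truncated lognormal
(defaults: log-location ln 1.85 / ln 1.95 mmol/L for men/women,
log-scale 0.28 / 0.30, truncated to [0.3, 6.0] mmol/L). The curve is
divided into 30 equal-probability quantile bands per sex; each band
becomes a subgroup ("super patient") whose baseline LDL-C is the
conditional mean within the band. Equal-probability banding with
conditional means preserves the population mean LDL-C exactly — that is
why it was chosen over equal-width banding. Subgroup weights are
`sex_share / n_per_sex` (default sex shares 0.617 men / 0.383 women).
All subgroups of a sex share one median entry age (65 men, 70 women)
and age deterministically by one year per cycle; the number of bands is
a parameter, not a constant.

Untreated LDL-C drifts upward by a sex-specific constant (0.02 / 0.025
mmol/L·year) in the base case. A scenario replaces this with a
regression-to-the-mean model over the first three cycles: the change is
a linear function of baseline LDL-C (negative coefficient), age and
sex, so low-LDL subgroups drift up while high-LDL subgroups drift down,
after which LDL-C is held constant. A floor of 0.1 mmol/L keeps the
risk equations well-defined for degenerate inputs.

## State space

States: one chronic ("post") state per event type — ischaemic stroke,
MI, unstable angina, elective coronary revascularisation, PAD /
non-coronary revascularisation — an event-year ("acute") phase per
event, and an absorbing dead state. TIA is a cost-only event with no
alive state: its rate times the at-risk occupancy accrues the acute TIA
cost each cycle.

Severity is ranked (stroke worst, then MI, unstable angina, elective
revascularisation, PAD). A person with a CVD history who suffers a new,
less severe event returns — after the event year — to the post state of
their earlier, worse event. A memoryless chain cannot represent that
with a single acute state per event, so acute phases are implemented as
tunnel states keyed by `(event, return-post)`; only pairs where the
return state is at least as severe as the event are reachable (15
tunnels). Reporting aggregates tunnels back to one acute state per
event. Acute states last exactly one cycle, carry the event's acute
cost, utility multiplier and elevated mortality, and remain at risk of
further events.

Everyone starts in post-event states (default: 34% post-elective-
revascularisation, 32% post-MI, 14% post-stroke, 12% post-PAD, 8%
post-unstable-angina).

## Risk equations

Relative risks per 1 mmol/L LDL-C reduction (95% CI): MACE composite
0.78 (0.76–0.80) — applied to unstable angina, PAD and TIA, which have
no separate estimate; elective coronary revascularisation 0.74
(0.71–0.79); ischaemic stroke 0.78 (0.69–0.80); MI 0.73 (0.67–0.80);
all-cause mortality 0.90 (0.87–0.93); CVD death 0.80 (0.74–0.87,
scenario only).

With `RR` per 1 mmol/L *reduction*, a subgroup at LDL-C `c` has annual
rate

```
R_x = R0 · RR^(−c)
```

so rates rise with cholesterol and fall by a factor `RR^d` when
treatment removes `d` mmol/L — consistent with the risk-reduction form
`1 − RR^(LDL·Tx)`. `R0`, the hypothetical rate at zero LDL-C, is
back-solved per (event, sex, age band) cell from the observed cohort
rate using the sex's subgroup weights and baseline LDL-C levels:
`R0 = R_all / Σᵢ wᵢ·RR^(−cᵢ)` (weights renormalised within the sex
cohort). The sign convention matters: written with a positive exponent
the same mixture identity would make treatment *increase* risk, which
contradicts both the monotone risk–cholesterol gradient the model
requires and the direction of every downstream result.

### Mortality calibration

All-cause mortality is modelled like an event rate, with the direct
treatment effect damped by a factor `k ∈ (0, 1]`: the per-mmol effect
becomes `RR_mort^k`, and the mortality baseline is back-solved with the
same mixture identity. Treated cohorts additionally avoid
high-mortality acute-event years, so applying the full direct effect
would double-count. `k` is calibrated by bisection so that a uniform
1 mmol/L reduction changes the model's overall death rate — deaths per
person-year across all subgroups over a 10-cycle follow-up window, an
approximation to trial follow-up — by exactly the target ratio 0.90
(tolerance 1e-4 on the ratio; the bisection objective is monotone
because a larger `k` strengthens the direct effect). Under the default
synthetic inputs `k ≈ 0.90`, i.e. roughly a tenth of the mortality
benefit is already delivered by the event-mediated channel. In the
CVD-mortality-only scenario the CVD share of deaths (default 0.5)
responds to LDL-C with RR 0.80 and the non-CVD share is a flat hazard;
no further calibration is applied there — restricting the effect to
the CVD share is itself the guard against double counting, and the
calibration target for that variant is not separately defined.

## Treatment pathway

Treatment effects (relative reductions versus placebo on background
statin, 95% CrI): ezetimibe −17.8% LDL-C (−23.7, −11.9) / −20.0%
non-HDL-C; inclisiran −51.3% (−61.9, −40.5) / −45.1%; PCSK9 inhibitors
−55.0% (−60.3, −49.4) / −47.0%. Effects compose multiplicatively on the
statin-background level (`(1−e₁)(1−e₂)`), the standard
proportional-reduction rule; composition order is immaterial. Whether
the original effects should instead re-anchor to the untreated baseline
is not determinable from the available material; the multiplicative
rule was chosen and is tested for order-invariance.

Escalation runs at each cycle start after drift and measurement. Up to
two lines can start in one cycle (configurable); lines are tried in
sequence order and the process stops as soon as the measured level is
at or below the threshold. The PCSK9-add-on scenario gives PCSK9 its
own absolute trigger (3.5 mmol/L) as a third line. Escalation decisions
use the subgroup's modelled mean level — a cohort-level model has no
measurement noise.

Partial adherence splits the escalating cohort into an adherent arm
(full drug cost and effect) and a non-adherent arm (neither cost nor
benefit, including no initiation visit, and the line is not re-offered).
The non-adherent arm continues the same cycle's escalation logic, so
zero adherence to ezetimibe is exactly equivalent to removing ezetimibe
from the sequence — an equivalence the tests assert. Arms whose
treatment status converges are merged to bound the arm count.

Monitoring: one lipid test per person-year alive; an initiation cycle
adds one re-test plus the initiation visit (GP appointment £38;
hospital outpatient visit £138 for PCSK9 initiation; a scenario charges
two GP visits and a nurse visit per inclisiran initiation).

## Transition mechanics

Annual rates convert to probabilities per alive state by
`p_any = 1 − exp(−R_total)` shared among competing causes (new events
and death) in proportion to their rates — the standard competing-risks
discretisation; rows therefore sum to 1 exactly and the engine raises
on any conservation violation beyond 1e-10. Acute-state occupants use
the admission-type-specific mortality of the last 12 months; post-state
occupants the chronic rate. The lifetime horizon caps age at 100 years
and stops when alive mass falls below 1e-9. No half-cycle correction is
applied by default (a config flag enables averaging start/end
occupancy); with a yearly cycle and lifetime horizon its effect is
second-order compared to the parameter uncertainty the PSA propagates.

## Costs and utilities

Unit costs (GBP): statin £1.40 and ezetimibe £1.47 per 28 tablets
(annualised ×365/28), lipid test £6, nurse visit £11, GP £38,
outpatient £138. Injectable prices are **placeholders** (inclisiran
£1,900/year invoice variant, £950 volume variant; PCSK9 £2,300/year) —
the real prices are commercial-in-confidence and nothing here claims
them. Acute event-year costs for stroke (including the payer share of
social care), MI and elective revascularisation are age/sex-specific
tables spanning £7,667–£14,632; unstable angina £8,835, non-coronary
revascularisation £2,720, TIA £3,196 flat; vascular deaths accrue
£3,196 in the event cycle. Chronic post-event annual costs use
published values where available (TIA £327, unstable angina £428) and
synthetic placeholders elsewhere (stroke £1,800, MI £520, elective
revascularisation £330, PAD £640) because the source regression-based
estimates are not published in usable form. Post-stroke social care
(£2,600/year synthetic) enters at a 50% payer share, the remainder
being out-of-pocket. Hooks exist for cost interaction terms between
events co-occurring within a year; their coefficients default to zero
since no usable published values exist.

Baseline EQ-5D utility is a synthetic, linearly declining age/sex curve
(0.87/0.85 at age 50, −0.0042/−0.0045 per year for men/women) standing
in for survey-based population norms. State utility multipliers
(mean ± SD): stroke acute 0.756 (0.064) / post 0.816 (0.013); MI 0.839
(0.054) / 0.847 (0.010); unstable angina 0.682 (0.021) / 0.878 (0.011);
elective revascularisation post 0.889 (0.028); PAD post 0.927 (0.016).
Events without an acute multiplier use their post value in the event
year. Two alternative multiplier sets used by scenarios are synthetic
variants (uniformly less and more generous), as the original sets are
not available. Costs and QALYs discount at 3.5%/year, cycle 0
undiscounted.

## Decision analysis and PSA

The sweep produces one deterministic, population-weighted result per
threshold (cost, QALYs, ezetimibe/injectable coverage among survivors
at one year, mean measured lipid level at one year). Incremental
analysis sorts by QALYs, removes strictly then extendedly dominated
options, requires strictly increasing ICERs along the frontier, and
selects the most effective option whose ICER does not exceed λ — which
provably equals the net-monetary-benefit arg-max; ties resolve to lower
cost, then lower threshold.

The PSA draws, independently per simulation: lognormal relative risks
and treatment-effect retention fractions — parameterised by matching
*both* printed 95% quantiles on the log scale, so draws reproduce the
printed intervals even where they are asymmetric around the point
estimate; beta utility multipliers (moment-matched to mean and SD);
gamma event/mortality rates and cost scale factors (means at the table
values, 95% half-width 20% by default — a package choice standing in
for unpublished cell-level standard errors). Parameters are drawn
independently (no published correlation structure); the mortality
calibration factor is held at its base-case value across simulations
rather than re-calibrated per draw. Simulations producing non-finite
output are rejected and counted, not truncated. "Probability
cost-effective" is the fraction of simulations in which a threshold
maximises NMB at λ, computable over the full grid or any configured
subset of thresholds. The default configuration runs 10,000
simulations.

Because the model is nonlinear in its parameters, PSA means carry a
genuine convexity bias relative to the deterministic run at the
parameter means (≈0.02 QALYs at the default ±20% spreads); this is
expected behaviour of E[f(θ)] versus f(E[θ]), not a Monte-Carlo defect,
and vanishes as the spreads narrow.

## Synthetic inputs: what they emulate and what they do not

The generator is a pure function of `(config, seed)` and reproduces the
structural features of linked primary-care/hospital/mortality data:
right-skewed LDL-C per sex; admission rates per person-year by event,
sex and 5-year age band that rise monotonically with age (base rates at
ages 65–69 between 0.005 and 0.016/year by event, growth factors
1.05–1.35 per band, ±1% seeded jitter that preserves monotonicity);
all-cause mortality rising roughly Gompertz-like (0.025/0.020 per year
at 65–69, growth 1.55/1.58 per band) with acute-context multipliers
(stroke ×5, MI ×4, PAD ×2.5, unstable angina ×2, elective
revascularisation ×1.3); and slow upward LDL-C drift.

It does **not** emulate: censoring and treatment-switching artefacts of
real record linkage, within-subgroup age heterogeneity, measurement
error in lipid tests, correlation between event and mortality rates,
seasonal or calendar effects, or real price schedules. Passing tests
therefore demonstrate the *correctness of the machinery* (conservation,
calibration, dominance logic, Monte-Carlo consistency) and the
*direction* of policy gradients, not the real-world location of the
optimal threshold, which depends on the confidential inputs.

## Problem sizes used by the test suite

The full base case (60 subgroups × 41 thresholds × lifetime) runs in a
few seconds and is exercised directly. The PSA tests use a reduced
bundle (2 subgroups per sex), a 5-point threshold grid and 300–1,000
simulations; the microsimulation oracle uses 5×10⁵ individuals on a
3-state, 5-cycle chain; distribution-matching oracles use 10⁵–10⁶
draws. These sizes were chosen to make the checks statistically sharp
while keeping the suite quick to run.

## Known limitations

* One post state per person: joint histories beyond the single most
  severe condition are not tracked, and interactions between
  concurrent conditions enter only through (default-zero) cost
  interaction hooks.
* The non-HDL-C mode maps levels to an LDL-C equivalent by a
  configurable affine offset (default −0.65 mmol/L) before applying
  the risk equations; the true mapping is population-dependent.
* The treatment-effect delay is not modelled: LDL-C reduction
  translates into risk reduction in the same cycle.
* Absolute costs, and hence optimal thresholds, reflect placeholder
  injectable prices and synthetic chronic-cost values.
* The statin-intolerant population is a stylised variant (no statin
  background, 30% higher untreated LDL-C, 10% mix weight), mixed with
  the base population by weighted averaging of per-threshold results
  before incremental analysis.
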