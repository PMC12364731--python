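# lipidcea

Cost-effectiveness modelling of cholesterol treatment-escalation
thresholds for the secondary prevention of cardiovascular disease
(CVD).

People with established CVD on a statin remain at high risk of further
events. Adding ezetimibe and, if needed, an injectable lipid-lowering
drug (inclisiran or a PCSK9 inhibitor) lowers LDL cholesterol further —
but at a cost. Health systems therefore need a *treatment-escalation
threshold*: the LDL-C (or non-HDL-C) level above which the next line of
therapy should be added. `lipidcea` is a cohort Markov model that sweeps
candidate thresholds on a 0.1 mmol/L grid, values each policy in
lifetime discounted costs (GBP) and QALYs, and identifies the most
cost-effective threshold at a given willingness-to-pay. It is written
for health economists and HTA analysts who want a transparent, tested,
fully scriptable implementation driven by synthetic, seeded inputs —
no access to confidential patient-level data or commercial drug prices
is required.

## The model

* **Population.** Each sex's baseline LDL-C distribution (right-skewed,
  truncated lognormal) is divided into 30 equal-probability subgroups
  ("super patients"), each with its own sex, median entry age, baseline
  LDL-C and population weight. Untreated LDL-C drifts slowly upwards
  over time (or regresses to the mean over three cycles in a scenario).
* **Risk.** Cholesterol-mediated risk follows the per-1-mmol/L relative
  risks of the statin-trial meta-analyses. Treatment lowering LDL-C by
  `LDL × Tx` mmol/L reduces event rates by `1 − RR^(LDL·Tx)`; a
  subgroup at level *c* has rate `R_x = R0 · RR^(−c)`, where the
  hypothetical zero-LDL rate `R0` is back-solved per (event, sex, age
  band) from the observed cohort rate
  `R_all = R0 · Σᵢ pᵢ · RR^(−cᵢ)`. A direct all-cause mortality effect
  (RR 0.90 per mmol/L) is applied as `RR^(k·LDL)` with `k` calibrated
  by bisection so the overall modelled mortality reduction matches the
  trial target without double-counting the event-mediated channel.
* **Dynamics.** A yearly-cycle Markov chain over acute (event-year) and
  chronic (post-event) states for ischaemic stroke, MI, unstable
  angina, elective coronary revascularisation and PAD, plus an
  absorbing dead state; TIA is costed without a dedicated state. After
  a new event, people settle in the post state of the more severe
  condition in their history. Annual rates convert to probabilities via
  `1 − exp(−R)` with proportional allocation among competing causes.
* **Pathway.** At each cycle start, lipids are measured; cohorts above
  the threshold escalate (ezetimibe → injectable), twice in one cycle
  if the first drug is not enough — but the cheaper drug alone is kept
  when it brings the level just below the threshold. Partial adherence
  splits cohorts into arms with no cost and no benefit for
  non-adherers.
* **Decision analysis.** Thresholds are ranked by QALYs; strictly and
  extendedly dominated options are removed; the optimum at
  willingness-to-pay λ maximises net monetary benefit
  `NMB = λ·QALY − cost`. A probabilistic sensitivity analysis (gamma
  for rates/costs, beta for utility multipliers, lognormal for relative
  risks and treatment effects; 10,000 simulations by default) yields
  the probability each threshold is cost-effective.

Injectable drug prices are confidential in the source setting; the
package ships clearly-labelled placeholder prices, so absolute costs
and the resulting optimal thresholds are illustrative of the method,
not of any real price negotiation.

## Worked example

```python
import lipidcea as L

bundle = L.synthesize_inputs(seed=1)          # synthetic study inputs
prepared = L.prepare_model(bundle)            # back-solve R0, calibrate k
print("mortality calibration k =", round(prepared.k, 4))

results = L.sweep_thresholds(bundle, prepared=prepared)
for r in results:
    if r.threshold in (2.0, 2.2, 3.0, 4.0):
        print(f"thr {r.threshold:3.1f}  QALYs {r.qaly:.3f}  "
              f"ez {100*r.frac_ezetimibe_1y:5.1f}%  "
              f"inj {100*r.frac_injectable_1y:5.1f}%  "
              f"LDL@1y {r.mean_ldl_1y:.2f}")

for lam in (15000.0, 20000.0, 30000.0):
    ia = L.incremental_analysis(results, lam)
    print(f"optimal at £{lam:,.0f}/QALY: {ia.optimal.threshold:.1f} mmol/L")
```

prints

```
mortality calibration k = 0.8965
thr 2.0  QALYs 7.409  ez  42.5%  inj  19.2%  LDL@1y 1.56
thr 2.2  QALYs 7.359  ez  30.5%  inj  12.6%  LDL@1y 1.68
thr 3.0  QALYs 7.253  ez   4.6%  inj   1.3%  LDL@1y 1.94
thr 4.0  QALYs 7.227  ez   0.0%  inj   0.0%  LDL@1y 1.99
optimal at £15,000/QALY: 3.4 mmol/L
optimal at £20,000/QALY: 3.0 mmol/L
optimal at £30,000/QALY: 2.5 mmol/L
```

Reading the output: lowering the escalation threshold treats more
people (the ezetimibe and injectable columns), pushes mean LDL-C at one
year down, and buys QALYs at increasing marginal cost — so the optimal
threshold falls as willingness-to-pay rises. The calibration factor
`k ≈ 0.90` damps the direct mortality effect because roughly a tenth of
the mortality benefit already arrives through prevented acute events.
With the synthetic inputs and placeholder injectable prices the optimal
thresholds land higher than they would under real confidential prices;
the *patterns* (monotone coverage, QALY and LDL gradients, the
willingness-to-pay ordering) are the scientifically meaningful output.

The same analyses are available from the shell:

```bash
lipidcea generate-inputs --seed 7 --out bundle/
lipidcea sweep --seed 7 --out results/           # threshold sweep + ICERs
lipidcea psa --seed 7 --n-sims 1000 --out results/
lipidcea scenario --id cvd_mortality --seed 7 --out results/
lipidcea report --results results/
```

Every run writes a `manifest.json` (seed, config hash, version) so any
result can be regenerated exactly.

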