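# coolcea

Cost-effectiveness analysis of therapeutic-hypothermia strategies after
out-of-hospital cardiac arrest.

Mild therapeutic hypothermia (32–34 °C) after return of spontaneous
circulation improves survival and neurologic outcome, but the cooling
modalities differ widely in cost and in how quickly and evenly they cool:
surface cooling blankets, iced-saline peritoneal lavage, and veno-venous
extracorporeal membrane oxygenation (V–V ECMO) used as a blood-contact
cooling circuit. `coolcea` implements a societal-perspective,
lifetime-horizon decision-analytic model comparing these three strategies
with conventional supportive care, for health-economics researchers and
policy analysts evaluating post-arrest care.

## The model

A cohort of resuscitated adults is assigned to one strategy and reaches one
of three states, fixed at six months and constant thereafter: good
neurologic outcome (CPC 1–2), poor outcome (CPC 3–4), or death. With
strategy-specific mortality *d* and probability *g* of a good outcome given
survival:

    P(good) = (1 − d)·g,   P(poor) = (1 − d)·(1 − g),   P(dead) = d

Each branch accrues a hospital episode (cooling consumables, sedation and
paralytics, ICU and floor days) in year 0, plus outcome-specific
post-hospital streams: good-outcome survivors receive an implantable
cardioverter-defibrillator and rehabilitation, then annual outpatient,
transport and caregiver costs over their life expectancy; poor-outcome
survivors accrue institutional care (a mix of chronic-ventilator and
long-term-care daily rates), outpatient costs and caregiver opportunity
costs. Future costs and QALYs are discounted at 3 %/yr, with annuities
accrued at cycle start:

    A(L, r) = Σ_{t=0}^{⌈L⌉−1} min(1, L − t)·(1 + r)^{−t}
    QALY(outcome) = u_outcome · A(L_outcome, r)

Strategies are compared by incremental cost-effectiveness ratio
(ICER = ΔCost/ΔQALY) along the efficiency frontier after removing strictly
and extendedly dominated options, and by net monetary benefit
(NMB = λ·QALY − Cost) at a willingness-to-pay λ, by default $100,000/QALY.
Parameter uncertainty is propagated by one-way/tornado/two-way sensitivity
analyses over the printed ranges and by probabilistic sensitivity analysis:
beta distributions for probabilities and utilities, gamma for costs and
durations, moment-matched so the mean equals the base case and the range
carries 95 % central mass, summarized as cost-effectiveness acceptability
curves (CEAC).

## Worked example

```python
from coolcea import base_case_config, evaluate_all, efficiency_frontier
from coolcea.cohort_model import calibrate_f_vent

cfg = calibrate_f_vent(base_case_config(), 118_340.0)  # conventional-care arm
for e in efficiency_frontier(evaluate_all(cfg)).entries:
    print(f"{e.name:18s} ${e.expected_cost:10,.0f}  {e.expected_qaly:.2f} QALY"
          f"  {e.status}" + (f"  ICER ${e.icer_vs_previous:,.0f}/QALY"
                             if e.icer_vs_previous else ""))
```

prints

```
Cooling Blankets   $   111,746  1.71 QALY  on_frontier
Conventional Care  $   118,340  1.29 QALY  dominated
Peritoneal Lavage  $   151,864  2.36 QALY  on_frontier  ICER $61,846/QALY
V-V ECMO           $   163,047  1.51 QALY  dominated
```

Cooling blankets are the cheapest strategy and dominate both conventional
care and V–V ECMO (cheaper and more effective); peritoneal lavage buys
0.65 extra QALYs at about $62k per QALY, under the usual $100k/QALY
threshold. The same analysis runs end to end from the shell:

```sh
coolcea reproduce --out-dir results/   # results table, frontier, tornado, CEAC
coolcea oneway --param shared/le_poor --out-dir results/
coolcea psa --iterations 10000 --seed 1 --out-dir results/
```

The packaged base case is also shipped as an editable YAML file
(`src/coolcea/data/base_case.yaml`); pass a modified copy via `--config`.

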