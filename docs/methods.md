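# Methods

## Model structure

`coolcea` evaluates a decision tree over a hypothetical cohort of adults
resuscitated from out-of-hospital sudden cardiac arrest. Each strategy arm
(conventional supportive care, cooling blankets, iced-saline peritoneal
lavage, V–V ECMO) leads to a chance node with three terminal states —
good neurologic outcome (CPC 1–2), poor outcome (CPC 3–4), dead — assigned
at six months and held constant thereafter. There are no state transitions
after assignment: no re-arrest, readmission, or cooling complications are
modelled (the cohort expectation is exact, no microsimulation is needed).
Expected cost and QALYs per strategy are the probability-weighted sums over
the three branches.

## Costing conventions

* The hospital episode — cooling consumables, sedation/paralytics, ICU days,
  floor days, and (for good outcomes) ICD implantation and a rehabilitation
  block — occurs in year 0 and is undiscounted.
* Sedation/paralytic cost applies to every cooled patient, including
  non-survivors, since cooling spans the first 48 h. Non-survivors accrue
  only the short non-survivor ICU stay; no floor or post-hospital costs.
* Survivor ICU stay is 3 days for conventional care and 5 days for cooled
  strategies (2 extra days for cooling and rewarming). The printed range
  (2–7 days) attaches to the cooled strategies; conventional care carries
  an assumed range of 1–5 days, since no range is printed for the uncooled
  arm.
* Recurring post-hospital items (outpatient care, transport, caregiver
  opportunity costs, institutional care) are annual totals repeated over the
  outcome-specific life expectancy and discounted. The caregiver clinic
  figure ($175) is treated as an annual total.
* Costs are present-value USD as printed in the source tables; no further
  inflation adjustment is applied.

## Discounting

Future costs and QALYs are both discounted at the same annual rate (base
3 %, range 0–5 %). Annuities use annual cycles accrued at cycle start with
a fractional final cycle and no half-cycle correction:

    A(L, r) = Σ_{t=0}^{⌈L⌉−1} min(1, L − t)·(1 + r)^{−t}
            = (1 − x^⌊L⌋)/(1 − x) + (L − ⌊L⌋)·x^⌊L⌋,  x = 1/(1+r)

This makes a one-year life expectancy undiscounted, so the poor-outcome
QALY equals the poor-outcome utility at any rate. The implementation
branches on x == 1.0 rather than r == 0 so rates below float resolution are
handled exactly.

## The poor-outcome care-mix fraction (`f_vent`)

The base case lists both a chronic-ventilator daily rate ($1,582) and a
long-term-care daily rate ($257) for poor-outcome survivors without stating
the mix. The model prices a poor-outcome institutional day at
`f_vent·vent_daily + (1 − f_vent)·ltc_daily`. Since expected cost is affine
in `f_vent`, `calibrate_f_vent` solves it exactly against a target total
cost for one arm; the shipped default (0.61946…) is the value at which the
conventional-care arm's expected cost equals its published total
($118,340). The fixture carries `f_vent` with a degenerate range so it does
not enter tornado or probabilistic analyses — it is a calibration constant,
not a measured quantity — but it is freely overridable in a config file.
Nursing-training and ECMO-specialist staffing are treated as already folded
into the per-patient cooling costs, as no separate amounts are printed.

## Parameters

Every uncertain input is a `Param{base, low, high, kind}` with
`low ≤ base ≤ high`; probabilities, utilities and rates live in [0, 1],
costs and durations are non-negative. Strategy-level parameters: mortality,
good-outcome probability given survival, cooling and sedation costs, ICU
and floor days. Shared parameters: daily hospital costs, post-hospital
streams, life expectancies (good 5.5 y, poor 1.0 y), utilities (good 0.76,
poor 0.35), and the discount rate. The default willingness-to-pay is
$100,000/QALY. Configs round-trip losslessly through YAML; unknown keys are
rejected and every violation names the offending field.

## Dominance and decision rules

The efficiency frontier sorts strategies by expected cost, removes strictly
dominated entries (some cheaper-or-equal strategy is at least as
effective), then iteratively removes extended-dominated entries (ICER not
below the next more effective option's), leaving strictly increasing
ICERs. Cost/QALY differences within an absolute 1e-9 count as ties.
`preferred_strategy` maximizes net monetary benefit; ties break toward
lower cost, then higher QALYs, then input order (the higher-QALY step is a
refinement needed so a cost-tied dominated strategy can never be preferred
at λ = 0, keeping the frontier/NMB equivalence exact). ICERs are carried at
full precision; rounding is presentation-layer only.

## Deterministic sensitivity analysis

One-way sweeps re-evaluate the whole model on an evenly spaced grid over a
parameter's range (default 21 points; two-way maps default 41×41 — desk
scale, under a second). The model is affine in every cost and utility
input, so those curves are straight lines; tests assert three-point
collinearity. The tornado measure is the maximal NMB across strategies at
the analysis threshold, evaluated at each parameter's low and high with all
others at base; bars sort by width and flag preference reversals. A
dedicated utility sweep varies the poor-outcome utility over an explicit
range (default 0.2–0.6) that may exceed its printed range.

## Probabilistic sensitivity analysis

Distribution families follow the standard convention: beta for
probabilities and utilities, gamma for costs and durations. Fits are
method-of-moments with a one-dimensional solve: the mean is pinned to the
base value (beta a = m·κ, b = (1−m)·κ; gamma shape κ, scale m/κ) and the
concentration κ is solved by bisection so the (low, high) range carries
95 % central probability mass (tolerance 1e-6 on mean and mass). If the
beta match is infeasible (base on the range boundary), a logit-normal with
matched median and 95 % interval is used and logged. Degenerate ranges and
all rate-kind parameters (the discount rate, `f_vent`) are held fixed —
rates are varied deterministically only. All parameters are sampled
independently (no correlation data exist); draws come from one seeded
`numpy` generator in the deterministic order of `config.param_ids()`, so a
given (config, n, seed) is bit-reproducible. Default 10,000 iterations;
the CLI's default seed is printed in its manifest. CEACs report, at each
threshold on a $0–200k grid (step $5k), the fraction of iterations in which
each strategy attains the maximal NMB under the same tie rule.

## Synthetic configurations and oracles

`synthetic_params.random_config` draws structurally valid random configs —
uniform bases within per-kind bounds, uniform half-widths, orderings
(u_good > u_poor, le_good > le_poor, non-survivor ≤ survivor ICU days)
enforced by construction — purely to exercise code paths; it does not
mimic arrest epidemiology, so passing fuzz tests demonstrates structural
correctness, not clinical realism. Two independent oracles back the tests:
a leaf-by-leaf enumeration of the decision tree sharing no code with the
main evaluator, and a brute-force frontier that marks a strategy on-frontier
iff it is the NMB argmax somewhere on a threshold grid built from all
pairwise incremental ratios with evaluation points just below and above
every knot (so no preference interval can be straddled).

## Known limitations

* Two outcome states only; CPC 3 and 4 are pooled, so long-term-care cost
  and life-expectancy heterogeneity within "poor" is not represented.
* The calibrated `f_vent` absorbs every unmodelled component of the
  conventional-care arm; cross-arm totals then agree with their published
  values to within ~3 %, but the calibration fixes the poor-outcome annual
  cost at ≈$432k/yr, which places the lavage→blankets preference crossover
  in poor-outcome life expectancy near 3.5 y rather than the ≈2.75–3.0 y
  reported by the original analysis (whose internal cost structure is not
  fully published). The qualitative reversal — lavage below the crossover,
  blankets beyond — is reproduced.
* Under the maximal-NMB tornado measure, shared life-expectancy and utility
  ranges (le_good 4–10 y, u_good 0.55–0.97) swing net benefit more than the
  outcome-probability ranges; analyses that report outcome probabilities as
  most influential implicitly use an incremental measure between the two
  frontier strategies, under which the lavage mortality range (0.13–0.56)
  ranks first.
* No complication, readmission or value-of-information modelling; no
  correlation between sampled parameters; other cooling modalities (ice
  packs, intravenous iced saline) are out of scope.
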