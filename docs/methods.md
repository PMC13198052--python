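# Methods

This note documents the models, rules and numerical conventions behind
`prehabcea`, and the design choices made where more than one defensible
convention exists.

## Evaluation model

The package evaluates a preoperative prehabilitation programme against
standard care over a 12-month postoperative horizon from a societal
perspective.  No discounting is applied (the horizon is ~1 year).
Total per-patient costs are the sum of three blocks:

1. **Intervention** — frailty screening (flat fee per intervention-arm
   patient), a shared decision-making (SDM) conference priced by
   attendee composition (base fee + per-physician + per-therapist
   tariffs), and supervised prehabilitation sessions priced per setting
   (mobile / outpatient / outpatient with transportation /
   part-inpatient / inpatient).  Control-arm intervention cost is
   identically 0: the screening those patients underwent determined
   trial eligibility only and was not standard care.  Staff/centre
   training costs are excluded as scale-dependent implementation costs.
2. **Index hospital stay** — the hospital bill plus an investment-cost
   reference per case plus expected statutory co-payments
   `(1 − exempt_share) · rate · min(length_of_stay, cap)` with defaults
   10 EUR/day, 28-day cap, 50% exemption share.  The exemption is a
   deterministic expected-value multiplier rather than per-patient
   random assignment — the assumption concerns a population share, and
   determinism keeps valuation reproducible.  The calendar-year cap is
   approximated as a per-stay cap (no stay-to-calendar mapping exists
   in the inputs).  Patients without the index surgery have cost 0.
3. **12-month follow-up** — a 16-item resource-use questionnaire
   (3-month recall, administered at 3/6/9/12 months) valued with
   standardised societal unit costs.  Informal care is valued by the
   substitution cost approach (professional-caregiver wage).
   Medication use is carried in the schema but never valued: no
   standardised unit costs exist for it.  The bundled unit-cost table
   is illustrative; real tariffs are supplied as a JSON config.

When a patient dies, every cost window whose assessment date falls on
or after the death date is zeroed; intervention costs (incurred
preoperatively) are retained.

## Effect measures

* **QALY**: the arithmetic mean of the four quarterly EQ-5D-5L
  utilities; utility is 0 at assessments on/after death.  There is no
  partial-quarter proration — the measure averages four discrete
  assessments rather than integrating a continuous trajectory.  The
  baseline utility is *not* part of the QALY; it is kept as a covariate
  for imputation and matching.
* **DCDL**: indicator that the 0–5 care-dependency grade at 12 months
  exceeds baseline.  Death sets the 12-month level to 5 and counts as
  deterioration regardless of baseline — including a baseline level of
  5, where the rule overrides the strict-increase reading (logged when
  it happens).  When a death date is known, the death rule takes
  precedence over any missing 12-month level.
* **WHODAS 2.0** (12 items, simple scoring): plain sum, 12 best to 60
  worst; death scores 60.

Utilities come from a pluggable EQ-5D-5L value set.  The bundled toy
tariff is the closed form `mean over dimensions of 1 − 0.25·(level−1)`
(anchors 1 and 0); national tariffs (e.g. the German set with anchors
1 and −0.661) are loaded from a JSON file that declares its anchors,
which the loader validates against the tabulated extremes.

## Cost processing

Each cost block except the intervention block is winsorised at the
97.5th empirical percentile, computed pooled across both arms
(arm-specific thresholds would treat the arms asymmetrically).
Winsorisation operates at the level at which costs are observed and
imputed — each follow-up category × visit-window component, plus the
index stay.  The quantile uses linear interpolation between order
statistics (numpy default); the convention matters for small blocks and
is fixed here.  Winsorisation precedes imputation, so imputation models
fit winsorised observables; the raw components are retained for the
no-winsorisation sensitivity analysis, which is the single switch
distinguishing `SA_COSTS` from `ITT`.  Totals are recomputed as exact
sums of components, so the reported totals are always additive.

## Missing data

Missing cost components and outcomes (all visits) are multiply imputed
by chained equations: per variable, a ridge-stabilised Bayesian linear
model on all other analysis variables with predictive-mean-matching
(PMM) draws from a 5-donor pool.  PMM is used for every variable type:
donor draws respect the zero-inflated cost distributions (pure
regression draws would produce negative costs) and keep binary/ordinal
variables on observed levels.  Structural sentinels — death day for
survivors, session counts in the control arm — are never imputed.
Death-rule values (post-death zeros, level 5, WHODAS 60) are filled
*before* imputation and treated as observed.  Variables with fewer than
8 observed values or constant observed values are filled with the
observed mode and logged; a variable with zero observed values is an
error.

Defaults: m = 20 imputed datasets, 10 sweeps each (conventional values;
both configurable).  The m completed datasets are combined **at the
individual level** before analysis: per-cell mean for continuous
variables, per-cell mode for ordinal ones with ties broken toward the
worse health state, and totals/aggregated outcomes recomputed from the
combined component-level data.  This combination averages away
between-imputation variance, so the bootstrap intervals understate the
full imputation uncertainty; a conventional Rubin's-rules pooling mode
(`pooling="rubin"`) is provided for comparison and reported alongside,
never asserted against, the individual-level intervals.

## Balance and matching

Baseline balance is screened with absolute standardised mean
differences (SMD); SMD ≥ 0.10 flags a need for adjustment.  The
per-protocol populations (≥ 15 supervised sessions; additionally
underwent surgery) and the delivery-setting subgroups are
post-randomisation selections of the intervention arm, so an equal-size
control group is chosen by 1:1 nearest-neighbour propensity matching
without replacement, after imputation/combination.  The main-effects
logistic model uses age, sex, BMI, Charlson index, frailty status,
baseline care level (dropped when the outcome is DCDL), baseline
EQ-5D-5L utility, cognition (MOCA total score) and baseline WHODAS,
plus the recruiting specialty as a one-hot model term rather than a
hard constraint.  Matched analyses are labelled non-randomised and
exploratory in every output.

Numerical conventions: treated units are processed in descending
propensity order with seed-determined tie-breaks; nearest neighbours
are found on the *pooled rank* of the score, which makes the matching
invariant to any strictly monotone transform of the propensity
(probability vs. linear predictor — a known source of cross-software
divergence); rank-distance ties go to the lower-ranked donor.  No
caliper is applied by default; an optional probability-scale caliper
sacrifices the transform invariance.  For ≤ 6 treated units the greedy
result is compared against exhaustive assignment enumeration in the
test suite and the distance regret reported.

## Inference

Within-arm bootstrap (arm sizes preserved, cost and effect resampled
jointly per patient) with B = 10,000 replicates by default.  Confidence
intervals are percentile intervals whose endpoints are order statistics
of the cloud (type-1 / inverted-CDF quantiles); BCa was deliberately
not made the default — the percentile interval is the simplest
defensible reading of "bootstrapped CIs".  ICERs are computed from raw,
unrounded values; rounding (half-up, EUR to integers, utilities and
percentages to two decimals) happens only at report rendering.

Verdicts by sign pattern of (ΔE, ΔC): more effective & more costly →
ICER (north-east); more effective & less costly → intervention
dominates; less effective & more costly → control dominates; less
effective & less costly → the ratio is reported with an explicit
south-west quadrant label.  ΔE exactly 0 yields an undefined-ICER
verdict (reported, never raised).

The CEAC uses the net-monetary-benefit rule with strict inequality,
P(λ·ΔE − ΔC > 0); DCDL effects are converted from percentage points to
proportions first, so λ is EUR per whole prevented deterioration.  An
alternative quadrant/ICER-threshold rule is implemented for comparison;
the two differ only on boundary replicates.  CEAC(0) + P(ΔC ≥ 0) = 1
exactly.  The curve is nondecreasing when all replicates have ΔE ≥ 0
but need not be monotone for general clouds.  Confidence ellipses on
the cost-effectiveness plane use the cloud mean and covariance with the
chi-square(2 df) radius; a collinear cloud sets a degenerate-ellipse
flag instead of failing.

## Synthetic trial generator

The generator emulates the study conditions of a large German
multicentre prehabilitation trial in (pre-)frail elective-surgery
patients aged ≥ 70: arm sizes 616/583, ~54% female, median age ~78,
median BMI ~27, 37% frail, ~76%/72% with baseline care level 0, median
MOCA 24, ~89% undergoing the index surgery, 90% receiving an SDM
conference, a delivered-setting mix of 0.8/13/66/4/15% (mobile /
outpatient / outpatient + transport / part-inpatient / inpatient), and
session counts with ~16% never starting, 81% reaching 15 sessions and a
median near 29/30.  Default 12-month mortality is 7.5%, the midpoint
implied by the trial's published survivor counts per arm; the death day
is uniform over the 12-month window because no mortality timing is
published.  Costs are zero-inflated gamma draws per questionnaire item
and window, calibrated so annual category means under the bundled unit
costs echo the published skewed cost pattern (hospital stays, informal
care and rehabilitation dominating; several categories with median 0).

EQ-5D-5L states are generated by thresholding a latent severity
trajectory (a shared patient-level beta component plus visit-level
noise, randomised rounding onto the 5-dimension grid), which induces
the visit-to-visit and baseline correlation that chained-equation
imputation exploits, and makes the toy-tariff utility *unbiased* for
the latent target — so a configured mean utility shift is recovered
exactly in expectation.  The three configurable arm effects are exact
by construction under no mortality/dropout: the utility shift
(IG − CG), the overall deterioration-probability reduction (CG − IG,
rescaled internally for the death rule), and the follow-up cost saving
in EUR (injected through the hospital-days item; the EUR calibration
assumes the bundled unit-cost table).  WHODAS at 12 months is linked to
the same latent severity, so it improves with the utility effect but is
not independently configurable.

Missingness is missing-at-random: per-visit masking logistic in age and
baseline WHODAS (centred so the marginal rate matches the configured
probability), an extra independent masking of the 3-month EQ-5D state
(that visit was largely a keep-in-touch contact in the emulated trial),
and no additional masking of death-truncated fields.

What the generator does **not** emulate: cost-block correlation
structure beyond the shared health latent (not published), informative
(MNAR) dropout, COVID-era delivery disruptions, per-session scheduling,
and SDM conference content.  Passing tests therefore demonstrate that
the pipeline recovers known effects under MAR with realistic skew and
mortality — not that it is robust to MNAR missingness or structurally
different cost dependence.

## Problem sizes in tests and the acceptance script

The test suite exercises full-size (616/583) generation but runs
imputation-heavy analyses at m = 3–5, 3–5 sweeps and B = 400–2,000 on
cohorts of 150–300 patients per arm; coverage of bootstrap intervals is
checked over 200 simulated trials at B = 2,000; parameter recovery uses
1,200 patients per arm.  The acceptance script runs the full pipeline
at the default arm sizes with m = 5, 5 sweeps and B = 10,000.  These
sizes were chosen to keep Monte-Carlo error well below the assertion
tolerances (3 standard errors) at interactive runtimes.

The worked example in the README is produced by:

```python
import numpy as np
import prehabcea as pc

records = pc.simulate_trial(pc.SimConfig(seed=1))
spec = pc.AnalysisSpec(variant="ITT", effect_kind="qaly", seed=1, m=5, iterations=5)
bundle = pc.run_analysis(records, spec, keep_cloud=False)
inc = bundle["incremental"]
print(f"n = {bundle['manifest']['n_ig']} IG / {bundle['manifest']['n_cg']} CG")
print(f"incremental cost : {inc['delta_cost']:8.0f} EUR  (95% CI {inc['ci_cost'][0]:.0f}; {inc['ci_cost'][1]:.0f})")
print(f"incremental QALY : {inc['delta_effect']:8.3f}      (95% CI {inc['ci_effect'][0]:.3f}; {inc['ci_effect'][1]:.3f})")
print(f"verdict          : {inc['verdict']}, ICER = {inc['icer']:.0f} EUR/QALY")
wtp = np.array(bundle["ceac"]["wtp"]); p = np.array(bundle["ceac"]["probability"])
print(f"P(cost-effective): {p[wtp==0][0]:.2f} at 0 EUR, {p[wtp==50000][0]:.2f} at 50,000 EUR, {p[wtp==100000][0]:.2f} at 100,000 EUR")
```

## Known limitations

* The individual-level combination of imputations is the primary mode
  because it mirrors the emulated analysis, but it understates
  imputation uncertainty; use `pooling="rubin"` to gauge the gap.
* The complete-case population is effect-specific (completeness is
  judged against the chosen outcome's requirements), so arm sizes
  differ between the QALY and DCDL complete-case analyses by design.
* Greedy nearest-neighbour matching is order-dependent and can be
  suboptimal relative to optimal (network-flow) matching; the regret is
  measured in tests but optimal matching is out of scope.
* The bundled unit costs and value set are illustrative; conclusions
  about real tariffs require supplying the corresponding config files.
* Subgroup analyses on matched, post-randomisation populations are
  exploratory and labelled as such; no multiplicity adjustment is made.
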