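# prehabcea

Trial-based economic evaluation of multimodal **prehabilitation** for
elderly (pre-)frail patients before elective surgery, from a societal
perspective — implemented as a tested, reusable Python pipeline.

Health economists evaluating prehabilitation alongside a randomised
trial face a stack of intertwined steps: valuing heterogeneous resource
use in EUR, constructing quality-adjusted life years (QALYs) from
EQ-5D-5L states, handling deaths and missing visits, taming skewed cost
data, matching non-randomised per-protocol populations, and quantifying
decision uncertainty. `prehabcea` implements that full stack — plus a
synthetic two-arm trial generator with the same data structure, so every
stage is testable without access to protected patient-level data.

## The statistics at the core

For intervention group IG and control group CG with per-patient total
costs *C* and effect *E*:

* **Incremental cost** ΔC = mean C(IG) − mean C(CG); **incremental
  effect** ΔE oriented so that positive favours the intervention — the
  QALY as IG − CG, while the deterioration of care-dependency level
  (DCDL, a 0–5 German care grade dichotomised as worsened / not) and the
  WHODAS 2.0 disability score are *inverted* (CG − IG) because lower is
  better.  The DCDL difference is the absolute risk reduction in
  percentage points.
* **ICER** = ΔC / ΔE when signs are unclear; **dominance** when one
  strategy is both more effective and less costly.
* **QALY** = mean of the four quarterly EQ-5D-5L utilities over the
  postoperative year (utility 0 from the date of death).
* **Uncertainty**: within-arm bootstrap of patients (default
  B = 10,000) gives percentile CIs, a cost-effectiveness plane with
  95% confidence ellipses, and acceptability curves
  CEAC(λ) = P(λ·ΔE − ΔC > 0) over willingness-to-pay λ ∈ [0, 100,000] EUR.

Around these sit: unit-cost valuation of a 16-item resource-use
questionnaire (informal care at substitution wages; medication carried
but unvalued), index-stay costs with statutory co-payments,
winsorisation of each cost block at the pooled 97.5th percentile,
chained-equation multiple imputation with individual-level combination,
standardised-mean-difference balance checks, and 1:1 nearest-neighbour
propensity matching for per-protocol and setting analyses.

## Worked example

```python
import prehabcea as pc

records = pc.simulate_trial(pc.SimConfig(seed=1))        # 616 IG / 583 CG
spec = pc.AnalysisSpec(variant="ITT", effect_kind="qaly", seed=1,
                       m=5, iterations=5)
bundle = pc.run_analysis(records, spec)
inc = bundle["incremental"]
```

prints (via the snippet in `docs/methods.md`):

```
n = 616 IG / 583 CG
incremental cost :     1327 EUR  (95% CI 69; 2565)
incremental QALY :    0.030      (95% CI 0.009; 0.050)
verdict          : icer, ICER = 44787 EUR/QALY
P(cost-effective): 0.02 at 0 EUR, 0.57 at 50,000 EUR, 0.92 at 100,000 EUR
```

Read: this synthetic intervention arm cost 1,327 EUR more per patient
over the year and gained 0.030 QALYs, i.e. 44,787 EUR per QALY; whether
that is acceptable depends on the willingness to pay — at 50,000 EUR
per QALY the intervention is cost-effective in 57% of bootstrap
replicates.  Variants `CC`, `PP15`, `PP15OP`, `SA_COSTS`, `SA_EFFECTS`
and sixteen subgroups run through the same `AnalysisSpec`.

The same works from a shell:

```bash
prehabcea simulate --seed 1 --out sim/
prehabcea run --data sim/records.csv --variant ITT --effect qaly --seed 1 --out out/
prehabcea report --in out/
```

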