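# admarkov

A Markov cohort health-economic model of the Alzheimer's disease (AD)
continuum, written for health economists and methodologists who want a
fully testable, registry-style pipeline: from longitudinal cognition data
to lifetime costs, QALYs, and the cost-effectiveness of hypothetical
disease-modifying treatments (DMTs).

Because national dementia-registry data cannot be redistributed, the
package ships a synthetic registry generator with known ground truth, so
every stage — cleaning, transition estimation, mortality modelling, cost
regression, cohort simulation, cost-effectiveness analysis, probabilistic
sensitivity analysis — can be validated end to end by parameter recovery.

## The model

Five health states: **AD-MCI → Mild → Moderate → Severe dementia → Death**,
with backward transitions allowed within dementia. A cohort of
N = 100,000 people with AD-MCI enters at age 60 and is propagated through
40 annual cycles with half-cycle correction; costs and QALYs are
discounted at 3% to net present values (SEK, 2016 price level).

The pieces, in the field's standard notation:

* **Progression risk.** A multi-year risk is converted to a constant
  annual risk by `p₁ = 1 − (1 − pₖ)^(1/k)`; the base case turns a 50%
  3-year AD-MCI→dementia risk into 20.6% per year. A time-dependent
  variant applies a relative decline d per model year:
  `p(t) = p₁ (1 − d)^(t−1)`.
* **Transitions within dementia.** An ordered-probit model of the
  one-year-ahead severity state with previous-state indicators and an
  age ≥ 75 shift, fitted by weighted maximum likelihood with
  inverse-probability-of-censoring weights (IPCW) that correct for
  severity-dependent drop-out.
* **Mortality.** A Weibull proportional-hazards model on the age
  time-scale yields hazard ratios for Mild/Moderate/Severe dementia vs
  very mild dementia (MMSE 27–30); one-year death probabilities are
  `1 − exp(−q(age) · HR)` on top of a general-population life table, with
  a direct-Weibull low-mortality variant.
* **Costs and utilities.** Annual societal costs follow a log-link gamma
  GLM in age and severity; utilities follow the linear age model
  `u = −0.002464 · age + 0.962679` with per-state decrements, so QALYs =
  person-years × utility.
* **Intervention.** A hypothetical DMT multiplies forward-progression
  probabilities in the treated states (AD-MCI, Mild) by (1 − RRR),
  RRR = 25% in the base case, at 50,000 SEK per treated person-year.
  Outcomes: ΔC, ΔQ, ICER = ΔC/ΔQ, NMB = λ·ΔQ − ΔC at willingness-to-pay
  λ = 600,000 SEK/QALY, NNT by horizon, and closed-form threshold prices.
* **PSA.** 1,000-iteration Monte-Carlo over intervention cost,
  progression, state costs/utilities and mortality (SE = 25% of the mean,
  gamma for costs, beta for probabilities, evaluated at age 71), yielding
  the cost-effectiveness acceptability curve.

## Worked example

```python
from admarkov import (reference_inputs, reference_intervention,
                      run_cohort, run_treated_cohort, compare)

inputs = reference_inputs()            # calibrated base case
base = run_cohort(inputs)
treated = run_treated_cohort(inputs, reference_intervention())
res = compare(base, treated, reference_intervention(), wtp=600_000)
```

With the calibrated reference inputs this prints (see
`examples/04_cohort_and_cea.py`):

```
mean survival: 19.13 years
cumulative dementia: 96.4%
NPV cohort cost at 40 y: 429,509 mSEK
incremental cost:     326,156 SEK/person
incremental QALYs:      0.726 /person
ICER:                 448,985 SEK/QALY
NMB at 600k SEK:      109,702 SEK/person
threshold price (budget neutral): 14,233 SEK/yr
```

Read: treating 100,000 AD-MCI patients with the hypothetical DMT costs an
extra ≈326 kSEK per person over 40 years and buys ≈0.73 QALYs per person,
an ICER below the 600 kSEK willingness-to-pay — cost-effective under the
assumed effect, but far from cost-saving (the treatment would have to
cost under ≈14 kSEK/year to pay for itself).

The `examples/` directory holds one short script per capability
(registry generation, cleaning/staging, estimation, cohort + CEA, PSA);
a thin CLI (`admarkov synth-registry|prep|estimate|run-model|cea|psa|all`)
wraps the same functions for shell use.

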