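# Methods

This note records the model, the synthetic data-generating process, the
estimation procedures, and the numerical and design choices behind
`admarkov`. It documents what the code computes; every number quoted here
is produced by the test suite or the example scripts.

## Cohort engine

The engine is a deterministic state-transition (Markov cohort) model over
{AD-MCI, Mild, Moderate, Severe dementia, Death}. Defaults: cohort
N = 100,000, start age 60, 40 one-year cycles, discount rate 3%/year.

**Transition structure.** The AD-MCI row places mass only on
{stay, Mild, Death}: entry into dementia happens exclusively through Mild
dementia, so incident dementia is accounted as the MCI→Mild flow. Within
dementia, a 3×3 row-stochastic matrix over living states governs the
year-ahead severity, including backward transitions (observed in registry
data even if theoretically implausible); a `no_backward` switch
redistributes backward mass to the diagonal for sensitivity analysis.
Mortality is overlaid per row: the death probability at the current age
and state takes the column for Death and the living-state mass is
rescaled by (1 − p_death). Row sums are validated to 1 within 1e−12 and
any negative entry after composition is an error, not a warning.

**Accrual.** Person-years, costs and QALYs accrue on the trapezoid
(half-cycle correction): the average of start- and end-of-cycle
occupancy. Costs and utilities are evaluated at the age at cycle start.
The accrual of cycle t (1-based) is discounted at exponent t; a
mid-cycle anchor (t − 0.5) is available via `discount_anchor="mid"` and
raises all NPVs by a factor (1+r)^0.5. The Death state accrues nothing;
the half-cycle average automatically credits half a year to people dying
during a cycle. Age advances one year per cycle for the whole cohort;
survivors at the horizon are reported, never forced to Death.

**Risk conversions.** Multi-year to annual risk:
p₁ = 1 − (1 − pₖ)^(1/k) (so 0.50 over 3 years → 0.206299 → printed
20.6%). The time-dependent sensitivity multiplies the annual risk by
(1 − d)^(t−1); with d = 0.10 the second model year is 18.5%.

**Death probability formula.** The base case composes life-table annual
death probabilities q(age) with severity hazard ratios as
`1 − exp(−q · HR)` — the annual *probability* enters the exponent
directly. This is deliberate and reproduced as such; the mathematically
cleaner rate conversion `1 − (1 − q)^HR` is available behind
`rate_based_death=True` but is not the default. The two differ by
O(q²·HR) and are numerically close at the q values of ages 60–90.
AD-MCI mortality equals the general population (HR 1).

## Estimation stack

The estimation half consumes a longitudinal registry (person, visit date,
age, MMSE, death date) and produces the engine inputs.

**Cleaning.** Rules are applied in a fixed order (record-level first:
invalid date, visit after death, duplicate date, visit before the
designated baseline; then short interval < 4 months since the previous
*kept* visit; person-level last: no baseline, no MMSE at all). The order
affects only how exclusions are attributed, not the surviving set, and
cleaning is idempotent. Unparseable dates are tallied, never raised.

**Annualization.** MMSE is linearly interpolated in days onto each
person's baseline-anchored annual grid. Beyond the last visit, linear
extrapolation from the last two visits covers at most 3 months — forward
only, never before baseline. Grid values stay fractional until staging,
where they are rounded half-up (20.5 → 21 → Mild) because the severity
cut-offs (Mild 21–30, Moderate 10–20, Severe 0–9; very mild 27–30 in the
4-level scheme used for mortality) are integer-based.

**Transitions and censoring.** Consecutive grid years form one-year
transitions carrying the age at the interval start; a death within one
year of the last grid point becomes a transition to Death; otherwise the
person is censored one year after the last available MMSE. The
continuation (non-drop-out) probability is modelled by a logistic
regression on current state and age; IPCW weights are the inverse
cumulative continuation probabilities, stabilized by the marginal
per-interval continuation frequency and truncated at the 99th percentile
by default (both switchable). Weights equal (p₁⋯pₖ)⁻¹ for interval k.

**Ordered probit.** The one-year-ahead living state is modelled as an
ordered probit with previous-state indicators (reference: the best level
present) and an age ≥ 75 indicator — age was found informative only as
this dichotomy, so no continuous age term is included. The weighted
log-likelihood is maximized directly (BFGS on cut-point increments in log
space, start values from marginal outcome frequencies); statsmodels'
OrderedModel has no observation weights and therefore serves as the
independent cross-check at unit weights (agreement to ~1e−3 in the test
suite). Death is excluded from the probit outcome: mortality is the
Weibull model's job, keeping the two risks separated as in the engine.

**Mortality.** Person-year episodes (entry age, exit age, event, state at
entry) are left-truncated at the entry age, i.e. age is the time-scale.
A Weibull accelerated-failure-time model (lifelines, `entry_col`) is
fitted with state indicators; because the Weibull family is closed under
both AFT and proportional hazards, hazard ratios are recovered as
HR = exp(−shape·β). Very mild dementia (MMSE 27–30) is the reference;
`merge_very_mild=True` pools it with Mild for the low-mortality variant,
whose engine mode predicts one-year death probabilities directly from the
fitted Weibull instead of the life table + HR composition. With heavy
left truncation in a narrow age window, shape and scale are only weakly
identified separately while the hazard level and the HRs remain well
identified; tests therefore check fitted hazards and HRs, not raw
shape/scale, in near-degenerate scenarios.

**Costs and utilities.** Annual societal costs: gamma GLM with log link
on age and severity (statsmodels); predictions are exp of the linear
predictor and positive by construction. Utilities: the linear age model
u(age) = −0.002464·age + 0.962679 minus a per-state decrement, the same
age slope in every state, clamped to the EQ-5D-3L range [−0.594, 1]. The
formula is applied to raw age by default; an `age_offset` (e.g. 25)
is exposed because the provenance of the fitted range is ambiguous, but
it is not the default.

## Synthetic registry generator

The generator is first-class, tested code with exact ground truth
(`ground_truth()`), not a fixture.

* **Severity process.** Each year the latent severity index is drawn as
  effect(previous state) + 0.2·1[age ≥ 75] + ε, ε ~ N(0,1), and cut at
  (0.77, 3.45) into Mild/Moderate/Severe — i.e. the annual severity
  process *is* the ordered-probit model the estimator targets, which
  makes recovery experiments exact. (A genuinely accumulating latent
  random walk would not have previous-*category* probit transitions;
  the redraw construction is the simplest process that does.) Default
  cut-points and effects give high stay-probabilities (0.78/0.80/0.90)
  with small backward rates, the pattern seen in registry data. MMSE is
  the latent percentile quantile-mapped into the state's MMSE band, so
  staging the emitted integer MMSE recovers the generated state exactly.
* **Visits.** Baseline plus annual follow-ups with Gaussian jitter
  (sd 1 month by default). Jittered visits make the annual-grid
  interpolation mix adjacent years' MMSE, which attenuates recovered
  probit parameters by a few hundredths; recovery experiments therefore
  run with jitter 0, and the attenuation at realistic jitter is a known,
  documented measurement effect.
* **Mortality.** Annual death probabilities come from a life table (or a
  Weibull baseline) with severity hazard ratios applied on the hazard
  scale, `1 − (1 − q)^HR`, so proportional hazards holds exactly. Under
  a Weibull baseline, death times within the year are drawn by exact
  inverse-CDF inversion, making the Weibull fit correctly specified in
  recovery tests. The life table's terminal age closes with q = 1;
  episodes at that closure age are an artefact of table closure, not of
  the hazard law. Death dates are known for all decedents (register
  linkage), including after drop-out.
* **Drop-out.** At each scheduled follow-up the person drops out with
  probability logit⁻¹(−2.5 + 0.8·severity level), where severity is the
  state at the most recent *completed* visit — the information set the
  censoring model conditions on, making IPCW correctly specified. The
  defaults give per-visit drop-out of roughly 8% (Mild) to 29% (Severe):
  strongly informative censoring.
* **Costs.** Annual costs are gamma draws (shape 4) around state means
  (250/340/480 kSEK by default) with a log-linear age trend.
* **Corruption.** Opt-in, labelled injection of the four defect classes
  the cleaner must catch (short interval, duplicate date, visit after
  death, all-MMSE-missing person), sampled from disjoint person sets so
  report counts are verifiable by construction.
* **Determinism.** All randomness flows from a single integer seed
  through numpy Generators; identical parameters give byte-identical
  CSV output.

What the generator does *not* emulate: diagnosis-type mixtures,
biomarkers, calendar-time effects, measurement error in MMSE beyond
discretization, practice variation between clinics, and drop-out
mechanisms that depend on unobserved decline. Passing recovery tests
shows the estimators are correct under the stated mechanisms, not that
real registry data satisfy them.

## Reference input set (calibration)

The per-state transition probabilities, costs and utilities of the
original registry-based analysis are not publicly deposited. The shipped
reference inputs are therefore a *calibration*, chosen once so that the
engine's headline behaviour is realistic for an AD-MCI cohort entering at
60: mean survival ≈ 19.1 years, cumulative dementia ≈ 96%, ≈ 54% dead by
year 20, lifetime per-state person-years ≈ (4.2, 4.9, 7.2, 2.8), NPV
cohort cost ≈ 430 bnSEK. Components: life table q(a) = 0.005·1.095^(a−60);
dementia matrix rows (0.78, 0.21, 0.01 / 0.03, 0.89, 0.08 / 0, 0.06,
0.94); hazard ratios 1.5/2.5/7.0; state costs 195/250/370/520 kSEK; state
utility decrements 0/0.14/0.30/0.50. They are labelled calibration
everywhere and never presented as registry estimates.

## Intervention and cost-effectiveness

The treatment multiplies forward-progression probabilities out of treated
states (AD-MCI and Mild by default) by (1 − RRR), adding the freed mass
to the stay probability; the death column and backward transitions are
untouched, so survival gains arise purely from spending longer in
lower-mortality states. "Slowing progression within Mild dementia" is
read as scaling Mild→Moderate and Mild→Severe only. Treatment cost
(50,000 SEK/year) accrues per half-cycle-corrected person-year spent in a
treated state within the treatment window (start age 60, duration 40
years), discounted like all other costs — not per initiated person.

All incremental measures are per-person NPVs. NNT at horizon h is
N / (avoided cumulative incident dementia cases by h), rounded half-up.
Because the treatment price enters the incremental cost linearly with
slope equal to the discounted treated person-years per person, the
budget-neutral price (ΔC = 0) and the NMB-zero price at a given
willingness to pay are solved in closed form from one model comparison;
the test suite confirms agreement with a bisection root to 1e−6 SEK.
When |ΔQ| falls below 1e−9 the ICER is flagged undefined rather than
reported; an NNT with no avoided cases is NaN, not an exception.

The scenario battery exposes every knob named in the main analysis: RRR ∈
{0.25, 0.5, 1.0}, treated states/start state, start age + horizon,
time-dependent risk decline, low-mortality mode, no-backward-transitions,
and discount rates 1%/3%/5%; unknown knobs fail loudly with the valid
list.

## Probabilistic sensitivity analysis

Parameters drawn per iteration, independently (no correlation structure
is asserted): intervention cost and state costs ~ gamma parameterized by
(mean, SE): shape = (mean/SE)², scale = SE²/mean; probabilities and state
utilities ~ beta moment-matched to (mean, SE), with the SE truncated to
the feasible range if needed; progression and mortality multipliers
~ gamma with mean 1. SE = 25% of the mean by default. Age-varying inputs
(life table, cost-age trend, utility-age slope) are frozen at their
age-71 values for PSA runs only. Both arms share each iteration's draws
(common random parameters). Draws derive from SeedSequence(seed,
iteration), so any iteration is reproducible in isolation. The CEAC
reports P(λ·ΔQ − ΔC > 0) over λ = 0 … 1.2 MSEK in 50 kSEK steps; ties
count as not cost-effective. Iteration failures are excluded with a
warning count rather than aborting the run.

## Numerical choices and problem sizes

* Engine occupancy is float64 matrix propagation; mass conservation is
  tested to 1e−9·N per cycle and the constant-input engine agrees with
  the matrix-power solution to 1e−10·N.
* The probit optimizer parameterizes cut-points as (c₁, log Δ) to keep
  them ordered; convergence failure raises with the optimizer message.
* Recovery experiments use cohorts of 5,000 individuals, seeds 1–5, and
  require the mean recovered parameter to lie within 3 Monte-Carlo
  standard errors (the SD of the seed replicates) of the generator truth;
  these sizes give sub-minute fits per model while keeping the MC SE a
  few times smaller than the parameters themselves.
* The PSA example and tests run 60–500 iterations; the default
  specification is 1,000.

## Known limitations

* The engine is a cohort model: no individual heterogeneity in age,
  progression or treatment response within a state, and no stopping
  rules conditional on individual trajectories (a microsimulation
  question).
* The reference input set is a calibration, so absolute cost/QALY levels
  carry no empirical authority; incremental comparisons and orderings are
  the meaningful outputs.
* IPCW corrects drop-out that depends on the observed state history
  only; drop-out driven by unobserved decline between visits would leave
  residual bias.
* The "(probability × HR)" death formula slightly overstates mortality
  at high q relative to the rate-based conversion; both are available.
* Currency is fixed at SEK 2016 (8.56 SEK/US$, 9.47 SEK/€); no inflation
  or PPP adjustment is performed.
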