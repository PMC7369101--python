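"""Probabilistic sensitivity analysis of the base intervention.

Parameter uncertainty is propagated by Monte-Carlo: each iteration draws
an independent parameter set (gamma distributions for costs, beta for
probabilities and utilities, standard error 25% of the mean by default),
re-runs both model arms on the drawn inputs, and records the incremental
cost and QALY pair. Parameters are evaluated at a fixed age-71 operating
point: age-varying inputs (life-table mortality, age-trended costs,
age-declining utilities) are frozen at their age-71 values for PSA runs
only. The cost-effectiveness acceptability curve (CEAC) reports, for each
willingness-to-pay level, the fraction of iterations with positive net
monetary benefit (ties count as not cost-effective).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .markov_core import ModelInputs, run_cohort
from .intervention_cea import (
    InterventionSpec,
    compare,
    run_treated_cohort,
)


class PsaConfigError(ValueError):
    pass


DEFAULT_LAMBDA_GRID = tuple(range(0, 1_200_001, 50_000))


@dataclass(frozen=True)
class PsaSpec:
    """PSA configuration.

    ``parameters`` lists which model quantities are drawn; each is
    perturbed around its base-case mean with SE = ``se_fraction`` * mean.
    Families: gamma for costs and positive scale factors, beta
    (moment-matched, SE truncated to feasibility) for probabilities and
    utilities.
    """

    iterations: int = 1000
    seed: int = 1
    se_fraction: float = 0.25
    operating_age: float = 71.0
    wtp: float = 600_000.0
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    parameters: tuple = (
        "intervention_cost",
        "mci_risk",
        "progression_scale",
        "state_costs",
        "state_utilities",
        "mortality_scale",
    )

    def __post_init__(self):
        if self.iterations < 1:
            raise PsaConfigError("iterations must be >= 1")
        if self.se_fraction < 0:
            raise PsaConfigError("se_fraction must be non-negative")


def gamma_draw(rng: np.random.Generator, mean: float, se: float, size=None):
    """Gamma draw parameterized by mean and SE: shape=(mean/se)^2, scale=se^2/mean."""
    if mean <= 0:
        raise PsaConfigError("gamma parameter mean must be positive")
    if se == 0:
        return mean if size is None else np.full(size, mean)
    shape = (mean / se) ** 2
    scale = se * se / mean
    return rng.gamma(shape, scale, size=size)


def beta_draw(rng: np.random.Generator, mean: float, se: float, size=None):
    """Moment-matched beta draw on (0, 1); SE truncated to feasibility."""
    if not 0 < mean < 1:
        raise PsaConfigError("beta parameter mean must be in (0, 1)")
    if se == 0:
        return mean if size is None else np.full(size, mean)
    max_sd = 0.99 * np.sqrt(mean * (1 - mean))
    se = min(se, max_sd)
    nu = mean * (1 - mean) / (se * se) - 1.0
    a, b = mean * nu, (1 - mean) * nu
    return rng.beta(a, b, size=size)


def frozen_inputs(inputs: ModelInputs, age: float) -> ModelInputs:
    """Freeze every age-varying input of the engine at ``age``.

    The life table collapses to a constant annual probability, costs to a
    per-state table evaluated at ``age``, and utilities to an
    age-constant model.
    """
    q = inputs.q_at(age)
    ages = inputs.life_table["age"]
    flat = pd.DataFrame({"age": ages, "q": np.full(len(ages), q)})
    costs = {
        s: inputs.cost_at(age, s) for s in ("MCI", "Mild", "Moderate", "Severe")
    }
    return replace(
        inputs,
        life_table=flat,
        state_costs=costs,
        utility=inputs.utility.frozen_at(age),
        dementia_matrix_age75=None,
        dementia_matrix=(
            inputs.dementia_matrix_age75
            if inputs.dementia_matrix_age75 is not None and age >= 75
            else inputs.dementia_matrix
        ),
        mortality_model=None,
    )


def draw_parameters(spec: PsaSpec, inputs: ModelInputs,
                    intervention: InterventionSpec, iteration: int) -> dict:
    """Independent parameter draws for one iteration (seed-reproducible)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, iteration]))
    f = spec.se_fraction
    draws: dict = {}
    if "intervention_cost" in spec.parameters:
        m = intervention.annual_cost
        draws["intervention_cost"] = (
            float(gamma_draw(rng, m, f * m)) if m > 0 else 0.0
        )
    if "mci_risk" in spec.parameters:
        m = inputs.mci_annual_risk
        draws["mci_risk"] = float(beta_draw(rng, m, f * m))
    if "progression_scale" in spec.parameters:
        draws["progression_scale"] = float(gamma_draw(rng, 1.0, f))
    if "state_costs" in spec.parameters:
        draws["state_costs"] = {
            s: float(gamma_draw(rng, inputs.cost_at(spec.operating_age, s),
                                f * inputs.cost_at(spec.operating_age, s)))
            for s in ("MCI", "Mild", "Moderate", "Severe")
        }
    if "state_utilities" in spec.parameters:
        frozen_u = inputs.utility.frozen_at(spec.operating_age)
        draws["state_utilities"] = {
            s: float(beta_draw(rng, np.clip(frozen_u.value(spec.operating_age, s),
                                            1e-3, 1 - 1e-3),
                               f * frozen_u.value(spec.operating_age, s)))
            for s in ("MCI", "Mild", "Moderate", "Severe")
        }
    if "mortality_scale" in spec.parameters:
        draws["mortality_scale"] = float(gamma_draw(rng, 1.0, f))
    return draws


def _apply_draws(base: ModelInputs, draws: dict) -> ModelInputs:
    over: dict = {}
    if "mci_risk" in draws:
        over["mci_annual_risk"] = draws["mci_risk"]
    if "state_costs" in draws:
        over["state_costs"] = draws["state_costs"]
    if "state_utilities" in draws:
        u = draws["state_utilities"]
        # re-express as an age-constant utility model with MCI as anchor;
        # enforce monotone non-increasing utilities across severity
        vals = [u["MCI"], u["Mild"], u["Moderate"], u["Severe"]]
        vals = list(np.minimum.accumulate(vals))
        dec = {s: vals[0] - v for s, v in
               zip(("MCI", "Mild", "Moderate", "Severe"), vals)}
        from .estimation import UtilityModel
        over["utility"] = UtilityModel(slope=0.0, intercept=vals[0],
                                       decrements=dec)
    if "progression_scale" in draws:
        m = np.asarray(base.dementia_matrix, dtype=float).copy()
        for i in range(3):
            fwd = m[i, i + 1:].sum()
            scaled = min(fwd * draws["progression_scale"], fwd + m[i, i])
            if fwd > 0:
                m[i, i + 1:] *= scaled / fwd
                m[i, i] -= scaled - fwd
        over["dementia_matrix"] = m
    if "mortality_scale" in draws:
        lt = base.life_table.copy()
        lt["q"] = np.clip(lt["q"] * draws["mortality_scale"], 0.0, 1.0)
        over["life_table"] = lt
    return replace(base, **over) if over else base


@dataclass
class PSAResult:
    """Per-iteration incrementals and acceptability summaries."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    wtp: float
    lambda_grid: tuple
    failures: int = 0

    @property
    def iterations(self) -> int:
        return self.delta_cost.size

    def probability_cost_effective(self, wtp: float | None = None) -> float:
        lam = self.wtp if wtp is None else wtp
        nmb = lam * self.delta_qaly - self.delta_cost
        return float(np.mean(nmb > 0.0))

    def ceac(self, lambda_grid: Sequence[float] | None = None) -> pd.DataFrame:
        grid = self.lambda_grid if lambda_grid is None else lambda_grid
        return ceac(self, grid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.iterations),
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
            }
        )


def ceac(result: PSAResult, lambda_grid: Sequence[float]) -> pd.DataFrame:
    """Acceptability curve: P(NMB > 0) per willingness-to-pay level.

    Ties (NMB exactly zero) count as not cost-effective.
    """
    if result.iterations < 1:
        raise ValueError("CEAC needs at least one successful iteration")
    rows = [
        (lam, float(np.mean(lam * result.delta_qaly - result.delta_cost > 0.0)))
        for lam in lambda_grid
    ]
    return pd.DataFrame(rows, columns=["wtp", "probability_cost_effective"])


def run_psa(
    spec: PsaSpec, inputs: ModelInputs, intervention: InterventionSpec
) -> PSAResult:
    """Run the PSA: common random parameters across the two arms.

    Each iteration re-runs control and treated arms on identically drawn
    inputs at the age-71 operating point. Iteration failures are recorded
    and excluded; the run continues.
    """
    base = frozen_inputs(inputs, spec.operating_age)
    dc, dq = [], []
    failures = 0
    for it in range(spec.iterations):
        draws = draw_parameters(spec, base, intervention, it)
        try:
            inp = _apply_draws(base, draws)
            sp = (
                replace(intervention, annual_cost=draws["intervention_cost"])
                if "intervention_cost" in draws
                else intervention
            )
            tb = run_cohort(inp)
            tt = run_treated_cohort(inp, sp)
            res = compare(tb, tt, sp, wtp=spec.wtp)
            dc.append(res.delta_cost)
            dq.append(res.delta_qaly)
        except Exception:
            failures += 1
    if failures:
        import warnings

        warnings.warn(f"{failures} PSA iteration(s) failed and were excluded")
    return PSAResult(
        delta_cost=np.asarray(dc),
        delta_qaly=np.asarray(dq),
        wtp=spec.wtp,
        lambda_grid=tuple(spec.lambda_grid),
        failures=failures,
    )
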