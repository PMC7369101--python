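"""Five-state Markov cohort engine for the AD continuum.

States: MCI, Mild, Moderate, Severe dementia, Death (absorbing). A
virtual cohort (default 100,000 people with AD-MCI, start age 60) is
propagated deterministically through 40 annual cycles. Per-cycle
person-years, costs and QALYs accrue on the half-cycle-corrected
occupancy (average of start- and end-of-cycle occupancy) and are
discounted to net present values at 3% per year by default.

Transition structure: MCI progresses only to Mild dementia (or stays, or
dies); within dementia, forward and - unless disabled - backward
transitions follow a row-stochastic severity matrix over living states;
the death column is overlaid from age- and severity-specific one-year
death probabilities, and the living-state mass is rescaled to 1 - p_death.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .states import SeverityState, ENGINE_STATES, ENGINE_LIVING_STATES
from .estimation import (
    CostModel,
    MortalityModel,
    TransitionModel,
    UtilityModel,
    death_probability,
)

_STATE_NAMES = tuple(s.value for s in ENGINE_STATES)
_LIVING = tuple(s.value for s in ENGINE_LIVING_STATES)
_DEMENTIA = ("Mild", "Moderate", "Severe")
N_STATES = len(_STATE_NAMES)
_I_MCI, _I_MILD, _I_MOD, _I_SEV, _I_DEATH = range(N_STATES)

ROW_SUM_TOL = 1e-12


def annualize_risk(p_multi: float, years: float) -> float:
    """Convert a multi-year risk to a constant annual risk.

    ``p_1year = 1 - (1 - p_multi)^(1/years)``: the annual probability
    whose constant repetition over ``years`` reproduces the multi-year
    risk. A 3-year risk of 0.50 gives an annual risk of 20.6%.
    """
    if not 0.0 <= p_multi <= 1.0:
        raise ValueError("p_multi must be in [0, 1]")
    if years <= 0:
        raise ValueError("years must be positive")
    return 1.0 - (1.0 - p_multi) ** (1.0 / years)


def time_dependent_risk(base: float, decline: float, cycle: int) -> float:
    """Annual risk in model year ``cycle`` under a relative yearly decline.

    ``risk_k = base * (1 - decline)^(k - 1)`` for cycle k >= 1: a 10%
    relative decline takes a 20.6% first-year risk to 18.5% in year two.
    """
    if not 0.0 <= decline < 1.0:
        raise ValueError("decline must be in [0, 1)")
    if cycle < 1:
        raise ValueError("cycle is 1-based")
    return base * (1.0 - decline) ** (cycle - 1)


def discount_factor(rate: float, t: float) -> float:
    """Present-value factor ``(1 + rate)^(-t)``."""
    if rate < 0 or t < 0:
        raise ValueError("rate and t must be non-negative")
    return (1.0 + rate) ** (-t)


@dataclass
class ModelInputs:
    """Complete parameter bundle for the cohort engine.

    ``dementia_matrix`` is the 3x3 row-stochastic one-year matrix over
    living dementia states (rows/cols Mild, Moderate, Severe) before
    mortality is overlaid; it may come from a fitted
    :class:`TransitionModel` via :meth:`from_transition_model`. Mortality
    is a life table plus per-state hazard ratios (MCI uses the life table
    directly, HR 1), or a fitted :class:`MortalityModel`. Costs are a
    per-state annual SEK mapping (2016 price level) or a fitted
    :class:`CostModel`.
    """

    dementia_matrix: np.ndarray
    life_table: pd.DataFrame
    hazard_ratios: Mapping[str, float]
    state_costs: Mapping[str, float] | CostModel
    utility: UtilityModel = field(default_factory=UtilityModel)
    cohort_size: int = 100_000
    start_age: int = 60
    horizon: int = 40
    discount_rate: float = 0.03
    mci_annual_risk: float = 0.206
    risk_decline: float = 0.0
    mortality_model: MortalityModel | None = None
    no_backward: bool = False
    start_state: str = "MCI"
    discount_anchor: str = "end"  # or "mid"
    rate_based_death: bool = False
    dementia_matrix_age75: np.ndarray | None = None

    def __post_init__(self):
        self.dementia_matrix = np.asarray(self.dementia_matrix, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.cohort_size <= 0:
            raise ValueError("cohort_size must be positive")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.discount_rate < 0:
            raise ValueError("discount rate must be non-negative")
        if not 0.0 <= self.mci_annual_risk <= 1.0:
            raise ValueError("mci_annual_risk must be a probability")
        if self.discount_anchor not in ("end", "mid"):
            raise ValueError("discount_anchor must be 'end' or 'mid'")
        if self.start_state not in _LIVING:
            raise ValueError(f"start_state must be one of {_LIVING}")
        for name, m in (("dementia_matrix", self.dementia_matrix),
                        ("dementia_matrix_age75", self.dementia_matrix_age75)):
            if m is None:
                continue
            m = np.asarray(m, dtype=float)
            if m.shape != (3, 3) or np.any(m < 0):
                raise ValueError(f"{name} must be 3x3 non-negative")
            if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError(f"{name} rows must sum to 1")

    @classmethod
    def from_transition_model(
        cls, model: TransitionModel, life_table, hazard_ratios, state_costs,
        age75_threshold: float = 75.0, **kwargs,
    ) -> "ModelInputs":
        """Build inputs using the probit-derived matrices by age group."""
        def submat(age_ge_75: bool) -> np.ndarray:
            full = model.transition_matrix(age_ge_75)
            sub = full.reindex(index=list(_DEMENTIA), columns=list(_DEMENTIA))
            sub = sub.fillna(0.0).to_numpy()
            rows = sub.sum(axis=1, keepdims=True)
            return sub / np.where(rows > 0, rows, 1.0)

        return cls(
            dementia_matrix=submat(False),
            dementia_matrix_age75=submat(True),
            life_table=life_table,
            hazard_ratios=hazard_ratios,
            state_costs=state_costs,
            **kwargs,
        )

    # -- per-age pieces ----------------------------------------------------
    def q_at(self, age: float) -> float:
        ages = self.life_table["age"].to_numpy()
        i = int(np.clip(np.searchsorted(ages, int(age), side="right") - 1,
                        0, len(ages) - 1))
        return float(self.life_table["q"].to_numpy()[i])

    def p_death(self, age: float, state: str) -> float:
        if self.mortality_model is not None and (
            self.mortality_model.mode == "direct_weibull"
        ):
            if state == "MCI":
                return death_probability(self.q_at(age), 1.0,
                                         rate_based=self.rate_based_death)
            return self.mortality_model.annual_death_probability(age, state)
        hr = 1.0 if state == "MCI" else float(self.hazard_ratios[state])
        return death_probability(self.q_at(age), hr,
                                 rate_based=self.rate_based_death)

    def cost_at(self, age: float, state: str) -> float:
        if hasattr(self.state_costs, "predict"):
            return float(self.state_costs.predict(age, state))
        return float(self.state_costs[state])


def build_transition_matrix(
    inputs: ModelInputs,
    age: float,
    cycle: int,
    row_modifier: Callable | None = None,
) -> np.ndarray:
    """Full 5x5 one-cycle matrix at a given age and model cycle.

    ``cycle`` is 1-based (first cycle = 1) and drives the optional
    time-dependent MCI progression risk. ``row_modifier(row, state,
    cycle, age) -> row`` hooks intervention effects in before validation.
    """
    M = np.zeros((N_STATES, N_STATES))
    p = time_dependent_risk(inputs.mci_annual_risk, inputs.risk_decline, cycle)

    pd_mci = inputs.p_death(age, "MCI")
    M[_I_MCI, _I_MCI] = (1.0 - p) * (1.0 - pd_mci)
    M[_I_MCI, _I_MILD] = p * (1.0 - pd_mci)
    M[_I_MCI, _I_DEATH] = pd_mci

    dm = inputs.dementia_matrix
    if inputs.dementia_matrix_age75 is not None and age >= 75.0:
        dm = np.asarray(inputs.dementia_matrix_age75, dtype=float)
    dm = np.asarray(dm, dtype=float).copy()
    if inputs.no_backward:
        # redistribute backward mass to the diagonal
        for i in range(3):
            back = dm[i, :i].sum()
            dm[i, :i] = 0.0
            dm[i, i] += back
    for i, s in enumerate(_DEMENTIA):
        pdth = inputs.p_death(age, s)
        M[1 + i, 1:4] = dm[i] * (1.0 - pdth)
        M[1 + i, _I_DEATH] = pdth
    M[_I_DEATH, _I_DEATH] = 1.0

    if row_modifier is not None:
        for i, s in enumerate(_STATE_NAMES[:-1]):
            M[i] = row_modifier(M[i], s, cycle, age)

    if np.any(M < -1e-15):
        raise RuntimeError("negative transition probability after composition")
    rows = M.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > 1e-9):
        raise RuntimeError(f"transition matrix rows not stochastic: {rows}")
    M = np.clip(M, 0.0, None)
    M /= M.sum(axis=1, keepdims=True)
    return M


@dataclass
class CohortTrajectory:
    """Per-cycle results of one engine run.

    Arrays are indexed by cycle (1..horizon maps to row 0..horizon-1);
    ``occupancy`` additionally holds the initial vector in row 0.
    Monetary streams are discounted (NPV); person-years are not.
    """

    inputs: ModelInputs
    occupancy: np.ndarray            # (T+1, 5)
    half_cycle_occ: np.ndarray       # (T, 4) living states
    discount: np.ndarray             # (T,)
    ages: np.ndarray                 # (T,) age at cycle start
    cost_by_state: np.ndarray        # (T, 4) discounted SEK
    qaly_by_state: np.ndarray        # (T, 4) discounted QALYs
    incident_dementia: np.ndarray    # (T,) MCI->Mild flow
    deaths_by_state: np.ndarray      # (T, 4) flow into Death by origin

    @property
    def state_names(self) -> tuple[str, ...]:
        return _STATE_NAMES

    @property
    def horizon(self) -> int:
        return self.half_cycle_occ.shape[0]

    def cumulative_incident_dementia(self, horizon: int | None = None) -> float:
        h = horizon or self.horizon
        return float(self.incident_dementia[:h].sum())

    def cumulative_deaths(self, horizon: int | None = None) -> np.ndarray:
        h = horizon or self.horizon
        return self.deaths_by_state[:h].sum(axis=0)

    def person_years(self, horizon: int | None = None) -> np.ndarray:
        """Undiscounted person-years by living state up to ``horizon``."""
        h = horizon or self.horizon
        return self.half_cycle_occ[:h].sum(axis=0)

    def total_cost(self, horizon: int | None = None) -> float:
        h = horizon or self.horizon
        return float(self.cost_by_state[:h].sum())

    def total_qalys(self, horizon: int | None = None) -> float:
        h = horizon or self.horizon
        return float(self.qaly_by_state[:h].sum())

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cycle export: cycle, state, occupancy, PY, cost, QALY."""
        rows = []
        for t in range(self.horizon):
            for i, s in enumerate(_LIVING):
                rows.append(
                    (t + 1, s, self.occupancy[t + 1, i],
                     self.half_cycle_occ[t, i],
                     self.cost_by_state[t, i], self.qaly_by_state[t, i])
                )
            rows.append((t + 1, "Death", self.occupancy[t + 1, _I_DEATH],
                         0.0, 0.0, 0.0))
        return pd.DataFrame(
            rows, columns=["cycle", "state", "occupancy", "person_years",
                           "cost_npv", "qaly_npv"]
        )


def run_cohort(
    inputs: ModelInputs, row_modifier: Callable | None = None
) -> CohortTrajectory:
    """Propagate the cohort and accrue half-cycle-corrected outcomes.

    Cycle t (1-based) advances the cohort from age ``start_age + t - 1``
    to ``start_age + t``; costs and utilities are evaluated at the age at
    cycle start, and the cycle's accrual is discounted at exponent ``t``
    (``t - 0.5`` under the mid-cycle anchor).
    """
    if inputs.horizon < 1:
        raise ValueError("horizon must be >= 1 for a trajectory")
    N = float(inputs.cohort_size)
    T = inputs.horizon
    occ = np.zeros((T + 1, N_STATES))
    occ[0, _STATE_NAMES.index(inputs.start_state)] = N
    half = np.zeros((T, 4))
    disc = np.zeros(T)
    ages = np.zeros(T)
    cost = np.zeros((T, 4))
    qaly = np.zeros((T, 4))
    incident = np.zeros(T)
    deaths = np.zeros((T, 4))

    for t in range(1, T + 1):
        age = inputs.start_age + t - 1
        M = build_transition_matrix(inputs, age, t, row_modifier)
        x = occ[t - 1]
        occ[t] = x @ M
        half[t - 1] = 0.5 * (x[:4] + occ[t, :4])
        exponent = t if inputs.discount_anchor == "end" else t - 0.5
        df = discount_factor(inputs.discount_rate, exponent)
        disc[t - 1] = df
        ages[t - 1] = age
        for i, s in enumerate(_LIVING):
            cost[t - 1, i] = half[t - 1, i] * inputs.cost_at(age, s) * df
            qaly[t - 1, i] = half[t - 1, i] * inputs.utility.value(age, s) * df
        incident[t - 1] = x[_I_MCI] * M[_I_MCI, _I_MILD]
        deaths[t - 1] = x[:4] * M[:4, _I_DEATH]

    return CohortTrajectory(
        inputs=inputs, occupancy=occ, half_cycle_occ=half, discount=disc,
        ages=ages, cost_by_state=cost, qaly_by_state=qaly,
        incident_dementia=incident, deaths_by_state=deaths,
    )


def summarize(
    trajectory: CohortTrajectory, horizons: Sequence[int] = (10, 20, 30, 40)
) -> pd.DataFrame:
    """Outcome table by horizon.

    Rows: cumulative dementia cases and deaths (total / with dementia /
    with MCI), mean person-years per person overall and by state,
    cumulative discounted costs and QALYs by state, and the NPV cost per
    person-year with dementia (dementia-state cumulative costs divided by
    dementia person-years).
    """
    N = trajectory.inputs.cohort_size
    out = {}
    for h in horizons:
        if h > trajectory.horizon:
            raise ValueError(f"horizon {h} exceeds trajectory ({trajectory.horizon})")
        pys = trajectory.person_years(h)
        deaths = trajectory.cumulative_deaths(h)
        costs = trajectory.cost_by_state[:h].sum(axis=0)
        qalys = trajectory.qaly_by_state[:h].sum(axis=0)
        dementia_py = pys[1:].sum()
        col = {
            "cumulative_dementia_cases": trajectory.cumulative_incident_dementia(h),
            "cumulative_deaths": deaths.sum(),
            "cumulative_deaths_dementia": deaths[1:].sum(),
            "cumulative_deaths_mci": deaths[0],
            "mean_py_per_person": pys.sum() / N,
            "mean_py_dementia": dementia_py / N,
        }
        for i, s in enumerate(_LIVING):
            col[f"mean_py_{s}"] = pys[i] / N
        for i, s in enumerate(_LIVING):
            col[f"cost_npv_{s}"] = costs[i]
        col["cost_npv_total"] = costs.sum()
        for i, s in enumerate(_LIVING):
            col[f"qaly_npv_{s}"] = qalys[i]
        col["qaly_npv_total"] = qalys.sum()
        col["cost_per_dementia_py"] = (
            costs[1:].sum() / dementia_py if dementia_py > 0 else float("nan")
        )
        out[h] = col
    return pd.DataFrame(out)
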