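"""Synthetic dementia-registry generator with known ground truth.

Emulates a national dementia quality registry: one row per clinic visit
(person id, visit date, age, MMSE, death date), together with a
general-population life table. Every statistical structure the estimation
stage targets is present by construction:

* annual severity transitions follow an ordered-probit model with
  previous-state indicators and an age>=75 shift,
* mortality is proportional-hazards on top of a life table (or an exact
  Weibull baseline), with severity-specific hazard ratios,
* drop-out is informative: a per-visit logistic function of the severity
  at the most recent completed visit,
* annual costs are gamma-distributed with state-specific means and a
  log-linear age trend,
* utilities decline linearly in age.

``ground_truth`` exposes the exact generating parameters so that
parameter-recovery experiments can measure estimator bias directly.
Opt-in corruption injects known counts of the defect classes the cleaning
stage must filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .states import SeverityState, DEMENTIA_STATES_3

_EPOCH = pd.Timestamp("2010-01-01")
_DAYS_PER_YEAR = 365.25
_DAYS_PER_MONTH = _DAYS_PER_YEAR / 12.0

#: MMSE band (low, high) per generated severity level, 3-level scheme.
_MMSE_BANDS = {
    SeverityState.MILD: (21, 30),
    SeverityState.MODERATE: (10, 20),
    SeverityState.SEVERE: (0, 9),
}


class ParameterError(ValueError):
    """Invalid generator parameters."""


@dataclass(frozen=True)
class MortalitySpec:
    """Mortality layer of the generator.

    Either a life table (annual death probabilities by integer age, death
    times drawn uniformly within the year) or a Weibull baseline hazard on
    the age time-scale (exact inverse-CDF death times), with severity
    hazard ratios relative to the mildest generated state.
    """

    hazard_ratios: Mapping[str, float] = field(
        default_factory=lambda: {"Mild": 1.0, "Moderate": 1.6, "Severe": 3.0}
    )
    life_table: pd.DataFrame | None = None
    weibull_shape: float | None = None
    weibull_scale: float | None = None

    def validate(self) -> None:
        hrs = [float(self.hazard_ratios[s.value]) for s in DEMENTIA_STATES_3]
        if any(h < 1.0 for h in hrs) or not (hrs[0] <= hrs[1] <= hrs[2]):
            raise ParameterError(
                "hazard ratios must be >= 1 and ordered Mild <= Moderate <= Severe"
            )
        if (self.weibull_shape is None) != (self.weibull_scale is None):
            raise ParameterError("weibull_shape and weibull_scale go together")
        if self.weibull_shape is not None and (
            self.weibull_shape <= 0 or self.weibull_scale <= 0
        ):
            raise ParameterError("Weibull shape and scale must be positive")


@dataclass(frozen=True)
class CorruptionSpec:
    """Counts of labelled defects to inject into the emitted registry."""

    short_interval: int = 0
    duplicate_date: int = 0
    after_death: int = 0
    missing_mmse: int = 0

    def total(self) -> int:
        return (
            self.short_interval
            + self.duplicate_date
            + self.after_death
            + self.missing_mmse
        )


@dataclass(frozen=True)
class GeneratorParams:
    """Ground-truth parameters of the synthetic registry.

    The probit layer: each year the latent severity index is drawn as
    ``effect[previous state] + age75_effect * 1[age >= 75] + N(0, 1)`` and
    discretized by ``probit_cutpoints`` into Mild/Moderate/Severe, which is
    exactly the ordered-probit transition model with previous-state
    covariates. MMSE is the latent index quantile-mapped into the state's
    MMSE band, so staging the emitted MMSE recovers the generated state.
    """

    n_individuals: int = 1000
    seed: int = 0
    # baseline age distribution (truncated normal), years
    baseline_age_mean: float = 76.0
    baseline_age_sd: float = 7.0
    baseline_age_min: float = 60.0
    baseline_age_max: float = 95.0
    # visit schedule
    visit_interval_months: float = 12.0
    visit_jitter_sd_months: float = 1.0
    # severity process (ordered probit)
    probit_cutpoints: tuple[float, ...] = (0.77, 3.45)
    probit_state_effects: Mapping[str, float] = field(
        default_factory=lambda: {"Mild": 0.0, "Moderate": 2.41, "Severe": 4.73}
    )
    age75_effect: float = 0.2
    baseline_state_probs: tuple[float, ...] = (0.55, 0.35, 0.10)
    # mortality
    mortality: MortalitySpec = field(default_factory=MortalitySpec)
    # drop-out (per scheduled follow-up visit, logit scale)
    dropout_intercept: float = -2.5
    dropout_severity_coef: float = 0.8
    # annual societal costs, SEK: per-state mean, gamma shape, log-age slope
    cost_state_means: Mapping[str, float] = field(
        default_factory=lambda: {
            "Mild": 250_000.0,
            "Moderate": 340_000.0,
            "Severe": 480_000.0,
        }
    )
    cost_gamma_shape: float = 4.0
    cost_age_coef: float = 0.005
    cost_age_center: float = 76.0
    # utility model
    utility_slope: float = -0.002464
    utility_intercept: float = 0.962679
    max_years: int = 45
    corruption: CorruptionSpec = field(default_factory=CorruptionSpec)

    def validate(self) -> None:
        if self.n_individuals < 0:
            raise ParameterError("n_individuals must be >= 0")
        if list(self.probit_cutpoints) != sorted(self.probit_cutpoints) or len(
            set(self.probit_cutpoints)
        ) != len(self.probit_cutpoints):
            raise ParameterError("probit cut-points must be strictly increasing")
        if len(self.probit_cutpoints) != len(DEMENTIA_STATES_3) - 1:
            raise ParameterError("need one fewer cut-point than severity levels")
        if abs(sum(self.baseline_state_probs) - 1.0) > 1e-9 or any(
            p < 0 for p in self.baseline_state_probs
        ):
            raise ParameterError("baseline_state_probs must be a probability vector")
        if self.visit_interval_months <= 0 or self.visit_jitter_sd_months < 0:
            raise ParameterError("visit schedule parameters out of range")
        if self.cost_gamma_shape <= 0 or any(
            m <= 0 for m in self.cost_state_means.values()
        ):
            raise ParameterError("cost means and gamma shape must be positive")
        if not self.baseline_age_min <= self.baseline_age_mean <= self.baseline_age_max:
            raise ParameterError("baseline age bounds must bracket the mean")
        self.mortality.validate()


@dataclass(frozen=True)
class TrueParameters:
    """Exact generating parameters, for recovery experiments."""

    probit_cutpoints: tuple[float, ...]
    probit_state_effects: dict
    age75_effect: float
    hazard_ratios: dict
    cost_state_means: dict
    cost_gamma_shape: float
    cost_age_coef: float
    dropout_intercept: float
    dropout_severity_coef: float
    utility_slope: float
    utility_intercept: float

    def transition_matrix(self, age_ge_75: bool = False) -> pd.DataFrame:
        """Probit-implied one-year matrix over living severity levels."""
        levels = [s.value for s in DEMENTIA_STATES_3]
        cuts = np.asarray(self.probit_cutpoints, dtype=float)
        rows = []
        for prev in levels:
            eta = self.probit_state_effects[prev] + (
                self.age75_effect if age_ge_75 else 0.0
            )
            cdf = stats.norm.cdf(np.concatenate([cuts - eta, [np.inf]]))
            probs = np.diff(np.concatenate([[0.0], cdf]))
            rows.append(probs)
        return pd.DataFrame(rows, index=levels, columns=levels)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)


def ground_truth(params: GeneratorParams) -> TrueParameters:
    """Return the exact parameters used by the generator."""
    return TrueParameters(
        probit_cutpoints=tuple(params.probit_cutpoints),
        probit_state_effects=dict(params.probit_state_effects),
        age75_effect=params.age75_effect,
        hazard_ratios=dict(params.mortality.hazard_ratios),
        cost_state_means=dict(params.cost_state_means),
        cost_gamma_shape=params.cost_gamma_shape,
        cost_age_coef=params.cost_age_coef,
        dropout_intercept=params.dropout_intercept,
        dropout_severity_coef=params.dropout_severity_coef,
        utility_slope=params.utility_slope,
        utility_intercept=params.utility_intercept,
    )


def generate_life_table(
    base_rate: float, growth: float, max_age: int = 105, start_age: int = 60
) -> pd.DataFrame:
    """Geometric life table: q(age) = min(1, base_rate * growth^(age-60)).

    The terminal age entry is forced to 1 so the table is a proper death
    distribution. ``growth >= 1`` keeps q non-decreasing with age.
    """
    if not 0 < base_rate < 1:
        raise ParameterError("base_rate must be in (0, 1)")
    if growth < 1:
        raise ParameterError("growth must be >= 1")
    ages = np.arange(start_age, max_age + 1)
    q = np.minimum(1.0, base_rate * growth ** (ages - start_age).astype(float))
    q[-1] = 1.0
    return pd.DataFrame({"age": ages, "q": q})


def weibull_life_table(shape: float, scale: float, max_age: int = 105,
                       start_age: int = 60) -> pd.DataFrame:
    """Life table implied by a Weibull hazard on the age time-scale.

    q(a) = 1 - exp(-(H(a+1) - H(a))) with H(a) = (a / scale)^shape.
    """
    if shape <= 0 or scale <= 0:
        raise ParameterError("shape and scale must be positive")
    ages = np.arange(start_age, max_age + 1)
    H = lambda a: (a / scale) ** shape  # noqa: E731
    q = 1.0 - np.exp(-(H(ages + 1.0) - H(ages.astype(float))))
    q[-1] = 1.0
    return pd.DataFrame({"age": ages, "q": np.clip(q, 0.0, 1.0)})


def _default_life_table() -> pd.DataFrame:
    # Calibration: Swedish-like general-population mortality from age 60.
    return generate_life_table(0.006, 1.093, max_age=110)


def _q_lookup(life_table: pd.DataFrame) -> tuple[int, np.ndarray]:
    ages = life_table["age"].to_numpy()
    return int(ages[0]), life_table["q"].to_numpy(dtype=float)


def _mmse_from_latent(state_idx: np.ndarray, u: np.ndarray,
                      cuts: np.ndarray) -> np.ndarray:
    """Quantile-map the latent percentile ``u`` into the state's MMSE band."""
    bounds = np.concatenate([[0.0], stats.norm.cdf(cuts), [1.0]])
    lo_u = bounds[state_idx]
    hi_u = bounds[state_idx + 1]
    r = np.clip((u - lo_u) / np.maximum(hi_u - lo_u, 1e-12), 0.0, 1.0)
    band = np.array([_MMSE_BANDS[s] for s in DEMENTIA_STATES_3])
    lo = band[state_idx, 0].astype(float)
    hi = band[state_idx, 1].astype(float)
    return np.clip(np.floor(hi - r * (hi - lo) + 0.5), 0, 30).astype(int)


def simulate_panel(params: GeneratorParams) -> pd.DataFrame:
    """Complete ground-truth annual panel (before observation effects).

    One row per person-year alive at the year start, with the true severity
    state, the emitted MMSE, the annual societal cost draw, and death
    information. Drop-out and visit jitter are applied later by
    :func:`generate_registry`; the panel itself is fully observed.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_individuals
    levels = list(DEMENTIA_STATES_3)
    cuts = np.asarray(params.probit_cutpoints, dtype=float)
    effects = np.array([params.probit_state_effects[s.value] for s in levels])
    hrs = np.array([params.mortality.hazard_ratios[s.value] for s in levels])
    life_table = (
        params.mortality.life_table
        if params.mortality.life_table is not None
        else (
            weibull_life_table(
                params.mortality.weibull_shape,
                params.mortality.weibull_scale,
                max_age=110,
            )
            if params.mortality.weibull_shape is not None
            else _default_life_table()
        )
    )
    lt_start, lt_q = _q_lookup(life_table)
    cost_means = np.array([params.cost_state_means[s.value] for s in levels])

    if n == 0:
        return pd.DataFrame(
            columns=[
                "person_id", "year", "age", "state", "mmse",
                "annual_cost", "died", "death_time",
            ]
        )

    a, b = (
        (params.baseline_age_min - params.baseline_age_mean) / params.baseline_age_sd,
        (params.baseline_age_max - params.baseline_age_mean) / params.baseline_age_sd,
    )
    age0 = stats.truncnorm.rvs(
        a, b, loc=params.baseline_age_mean, scale=params.baseline_age_sd,
        size=n, random_state=rng,
    )
    state = rng.choice(len(levels), size=n, p=np.asarray(params.baseline_state_probs))
    u0 = rng.uniform(size=n)
    bounds = np.concatenate([[0.0], stats.norm.cdf(cuts), [1.0]])
    u = bounds[state] + u0 * (bounds[state + 1] - bounds[state])
    mmse = _mmse_from_latent(state, u, cuts)

    alive = np.ones(n, dtype=bool)
    death_time = np.full(n, np.nan)
    records = []
    for year in range(params.max_years):
        idx = np.where(alive)[0]
        if idx.size == 0:
            break
        age = age0[idx] + year
        cost_mu = cost_means[state[idx]] * np.exp(
            params.cost_age_coef * (age - params.cost_age_center)
        )
        cost = rng.gamma(
            params.cost_gamma_shape, cost_mu / params.cost_gamma_shape
        )
        # death during (year, year+1] given state at year start
        ai = np.clip(np.floor(age).astype(int) - lt_start, 0, lt_q.size - 1)
        q = lt_q[ai]
        hr = hrs[state[idx]]
        p_die = 1.0 - (1.0 - q) ** hr
        u_die = rng.uniform(size=idx.size)
        dies = u_die < p_die
        frac = rng.uniform(size=idx.size)
        if params.mortality.weibull_shape is not None:
            # exact conditional death time under the Weibull baseline
            k, lam = params.mortality.weibull_shape, params.mortality.weibull_scale
            H_a = (age / lam) ** k
            # S(age+t)/S(age) = 1 - frac * p_die  =>  solve for t
            target = H_a - np.log1p(-frac * p_die) / hr
            t_in_year = np.clip(lam * target ** (1.0 / k) - age, 0.0, 1.0)
        else:
            t_in_year = frac
        records.append(
            pd.DataFrame(
                {
                    "person_id": idx,
                    "year": year,
                    "age": age,
                    "state": [levels[s].value for s in state[idx]],
                    "mmse": mmse[idx],
                    "annual_cost": cost,
                    "died": dies,
                    "death_time": np.where(dies, year + t_in_year, np.nan),
                }
            )
        )
        death_time[idx[dies]] = year + t_in_year[dies]
        alive[idx[dies]] = False
        # next year's severity for survivors
        idx2 = np.where(alive)[0]
        if idx2.size == 0:
            continue
        # age>=75 shift anchored at the interval start (the from-year age),
        # matching the transition records the estimator sees
        eta = (
            effects[state[idx2]]
            + params.age75_effect * (age0[idx2] + year >= 75.0)
        )
        eps = rng.standard_normal(idx2.size)
        y = eta + eps
        new_state = np.searchsorted(cuts, y, side="left")
        u_new = stats.norm.cdf(y)
        mmse[idx2] = _mmse_from_latent(new_state, u_new, cuts)
        state[idx2] = new_state

    panel = pd.concat(records, ignore_index=True)
    dt = pd.Series(death_time, name="death_time_person")
    panel = panel.merge(
        dt.rename_axis("person_id").reset_index(), on="person_id", how="left"
    )
    panel["baseline_age"] = age0[panel["person_id"].to_numpy()]
    return panel


def generate_registry(params: GeneratorParams) -> pd.DataFrame:
    """Emit the observed registry table from the ground-truth panel.

    Applies the visit schedule (annual target visits with Gaussian jitter),
    informative drop-out at follow-up visits, and optional labelled
    corruption. Returns a DataFrame with columns ``person_id, visit_date,
    age_at_visit, mmse, death_date``; `attrs` carry the injected-defect
    counts and the drop-out events ``(person_id, year, last_state)``.
    """
    params.validate()
    panel = simulate_panel(params)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    if panel.empty:
        out = pd.DataFrame(
            columns=["person_id", "visit_date", "age_at_visit", "mmse", "death_date"]
        )
        out.attrs["injected_defects"] = asdict(params.corruption)
        out.attrs["dropout_events"] = pd.DataFrame(
            columns=["person_id", "year", "last_state"]
        )
        return out

    n = params.n_individuals
    base_offset = rng.integers(0, 365, size=n)
    baseline_date = _EPOCH + pd.to_timedelta(base_offset, unit="D")
    sev_idx = {s.value: i for i, s in enumerate(DEMENTIA_STATES_3)}

    rows = []
    dropout_events = []
    interval_days = params.visit_interval_months * _DAYS_PER_MONTH
    for pid, grp in panel.groupby("person_id", sort=True):
        grp = grp.sort_values("year")
        bdate = baseline_date[pid]
        death_t = grp["death_time_person"].iloc[0]
        death_date = (
            bdate + pd.to_timedelta(round(death_t * _DAYS_PER_YEAR), unit="D")
            if np.isfinite(death_t)
            else pd.NaT
        )
        dropped = False
        last_state = grp["state"].iloc[0]
        prev_date = None
        for _, r in grp.iterrows():
            year = int(r["year"])
            if year == 0:
                vdate = bdate
            else:
                if dropped:
                    break
                p_drop = 1.0 / (
                    1.0
                    + np.exp(
                        -(
                            params.dropout_intercept
                            + params.dropout_severity_coef * sev_idx[last_state]
                        )
                    )
                )
                if rng.uniform() < p_drop:
                    dropped = True
                    dropout_events.append((pid, year, last_state))
                    break
                jitter = rng.normal(0.0, params.visit_jitter_sd_months) * _DAYS_PER_MONTH
                vdate = bdate + pd.to_timedelta(
                    round(year * interval_days + jitter), unit="D"
                )
                if prev_date is not None and vdate <= prev_date:
                    vdate = prev_date + pd.Timedelta(days=1)
                if death_date is not pd.NaT and vdate > death_date:
                    break
            rows.append(
                {
                    "person_id": pid,
                    "visit_date": vdate,
                    "age_at_visit": r["baseline_age"]
                    + (vdate - bdate).days / _DAYS_PER_YEAR,
                    "mmse": int(r["mmse"]),
                    "death_date": death_date,
                }
            )
            prev_date = vdate
            last_state = r["state"]

    out = pd.DataFrame(rows)
    out["mmse"] = out["mmse"].astype("Int64")
    out = _inject_corruption(out, params.corruption, rng)
    out.attrs["injected_defects"] = asdict(params.corruption)
    out.attrs["dropout_events"] = pd.DataFrame(
        dropout_events, columns=["person_id", "year", "last_state"]
    )
    return out


def _inject_corruption(
    df: pd.DataFrame, spec: CorruptionSpec, rng: np.random.Generator
) -> pd.DataFrame:
    if spec.total() == 0:
        return df
    df = df.copy()
    extra = []
    used: set = set()

    def pick(k: int, pool: np.ndarray) -> np.ndarray:
        pool = np.array([p for p in pool if p not in used])
        if len(pool) < k:
            raise ParameterError(
                f"not enough eligible persons to inject {k} defects"
            )
        chosen = rng.choice(pool, size=k, replace=False)
        used.update(chosen.tolist())
        return chosen

    persons = df["person_id"].unique()
    # visits < 4 months after an existing one
    for pid in pick(spec.short_interval, persons):
        row = df[df["person_id"] == pid].iloc[0].copy()
        row["visit_date"] = row["visit_date"] + pd.Timedelta(days=61)
        if pd.notna(row["death_date"]) and row["visit_date"] > row["death_date"]:
            row["visit_date"] = row["death_date"] - pd.Timedelta(days=1)
        extra.append(row)
    # exact duplicate dates
    for pid in pick(spec.duplicate_date, persons):
        row = df[df["person_id"] == pid].iloc[0].copy()
        extra.append(row)
    # follow-ups dated after death
    dead = df.loc[df["death_date"].notna(), "person_id"].unique()
    for pid in pick(spec.after_death, dead):
        row = df[df["person_id"] == pid].iloc[-1].copy()
        row["visit_date"] = row["death_date"] + pd.Timedelta(days=90)
        extra.append(row)
    if extra:
        df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True)
    # persons with all MMSE missing (disjoint from the other defect classes)
    for pid in pick(spec.missing_mmse, persons):
        df.loc[df["person_id"] == pid, "mmse"] = pd.NA
    df = df.sort_values(["person_id", "visit_date"], kind="stable").reset_index(
        drop=True
    )
    return df


def write_registry_csv(df: pd.DataFrame, path) -> None:
    """Write the registry table as CSV with ISO-8601 dates."""
    out = df.copy()
    for col in ("visit_date", "death_date"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_registry_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"mmse": "Int64"})
    df["visit_date"] = pd.to_datetime(df["visit_date"], errors="coerce")
    df["death_date"] = pd.to_datetime(df["death_date"], errors="coerce")
    return df


def write_life_table_csv(life_table: pd.DataFrame, path) -> None:
    life_table.to_csv(path, index=False)


def read_life_table_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
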