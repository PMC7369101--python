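"""Statistical models fitted to (synthetic) registry data.

Four fitted models feed the cohort engine:

* a logistic censoring model and inverse-probability-of-censoring weights
  (IPCW) correcting the transition sample for informative drop-out,
* a weighted ordered-probit model of the one-year-ahead cognitive state
  given the previous state and an age>=75 indicator (death is handled
  separately by the mortality model),
* a Weibull proportional-hazards mortality model on the age time-scale
  with severity hazard ratios relative to very mild dementia,
* a log-link gamma GLM for annual societal costs in age and severity,

plus the linear age-utility model used for QALY weighting.

The ordered-probit likelihood is maximized directly (scipy) because the
IPCW weights must enter the log-likelihood; the unweighted special case is
cross-checked against statsmodels' OrderedModel in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .states import (
    SeverityState,
    SEVERITY_ORDER,
    severity_rank,
)


class FittingError(RuntimeError):
    """A model failed to fit; the message carries diagnostics."""


# ---------------------------------------------------------------------------
# censoring model + IPCW
# ---------------------------------------------------------------------------

@dataclass
class CensoringModel:
    """Logistic model of remaining under observation next interval."""

    params: pd.Series
    state_levels: tuple[str, ...]
    reference_state: str

    def _design(self, state: pd.Series, age: pd.Series) -> pd.DataFrame:
        X = pd.DataFrame({"Intercept": np.ones(len(state), dtype=float)})
        for s in self.state_levels:
            if s != self.reference_state:
                X[f"state_{s}"] = (state.to_numpy() == s).astype(float)
        X["age"] = np.asarray(age, dtype=float)
        return X[self.params.index]

    def predict_continuation(self, state, age) -> np.ndarray:
        """P(next interval observed | current state, age), in (0, 1)."""
        state = pd.Series(np.atleast_1d(state))
        age = pd.Series(np.atleast_1d(age))
        eta = self._design(state, age).to_numpy() @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    @property
    def severity_coefficients(self) -> dict:
        return {
            k.removeprefix("state_"): v
            for k, v in self.params.items()
            if k.startswith("state_")
        }


def fit_censoring_model(intervals: pd.DataFrame) -> CensoringModel:
    """Fit the drop-out (continuation) model on person-intervals.

    ``intervals`` needs columns ``from_state``, ``age`` and ``observed``
    (True when the next grid state or death was observed). Intervals that
    end in observed death are not at risk of drop-out and should be
    excluded by the caller when that distinction matters; here every row
    is used as supplied.
    """
    df = intervals.copy()
    y = df["observed"].astype(int)
    if y.nunique() < 2:
        if y.iloc[0] == 1:
            # no censoring at all: continuation probability 1 everywhere
            levels = tuple(sorted(df["from_state"].unique(), key=severity_rank))
            params = pd.Series({"Intercept": 30.0, "age": 0.0})
            for s in levels[1:]:
                params[f"state_{s}"] = 0.0
            return CensoringModel(params, levels, levels[0])
        raise FittingError("censoring model needs >= 2 distinct outcomes")
    levels = tuple(sorted(df["from_state"].unique(), key=severity_rank))
    ref = levels[0]
    X = pd.DataFrame({"Intercept": 1.0}, index=df.index)
    for s in levels[1:]:
        X[f"state_{s}"] = (df["from_state"] == s).astype(float)
    X["age"] = df["age"].astype(float)
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    except Exception as exc:  # pragma: no cover - statsmodels raise paths
        raise FittingError(f"censoring model failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise FittingError(
            "censoring model did not converge (possible complete separation); "
            f"params={res.params.to_dict()}"
        )
    return CensoringModel(res.params, levels, ref)


def ipcw_weights(
    intervals: pd.DataFrame,
    model: CensoringModel | None = None,
    continuation: np.ndarray | None = None,
    stabilize: bool = True,
    truncate_percentile: float | None = 99.0,
) -> pd.Series:
    """IPCW weight per interval: inverse cumulative continuation probability.

    For person-interval k (1-based within person), weight =
    prod_{j<=k} 1 / p_j, optionally stabilized by the marginal per-interval
    continuation frequency and truncated at a percentile. Requires
    ``person_id`` and ``grid_year`` columns; rows must be supplied for the
    intervals actually used downstream.
    """
    df = intervals.sort_values(["person_id", "grid_year"], kind="stable")
    if continuation is None:
        if model is None:
            raise ValueError("either a censoring model or probabilities required")
        continuation = model.predict_continuation(df["from_state"], df["age"])
    p = np.asarray(continuation, dtype=float)
    if np.any(p <= 0):
        raise ValueError("continuation probabilities must be positive")
    p = np.minimum(p, 1.0)
    grp = df.groupby("person_id", sort=False).cumcount()
    logcum = pd.Series(np.log(p), index=df.index).groupby(
        df["person_id"], sort=False
    ).cumsum()
    w = np.exp(-logcum)
    if stabilize:
        # marginal continuation frequency by interval index
        obs = df["observed"].astype(float)
        marg = obs.groupby(grp.values).transform("mean").clip(1e-6, 1.0)
        logmarg = pd.Series(np.log(marg.to_numpy()), index=df.index).groupby(
            df["person_id"], sort=False
        ).cumsum()
        w = w * np.exp(logmarg)
    if truncate_percentile is not None:
        w = np.minimum(w, np.percentile(w, truncate_percentile))
    return pd.Series(w, index=df.index, name="weight").reindex(intervals.index)


# ---------------------------------------------------------------------------
# ordered probit transition model
# ---------------------------------------------------------------------------

@dataclass
class TransitionModel:
    """Ordered-probit one-year transition model over living states.

    ``levels`` are the ordered cognitive states (best to worst); the
    linear predictor holds previous-state indicators (reference = best
    level) and an age>=75 indicator. ``cutpoints`` are strictly
    increasing.
    """

    levels: tuple[str, ...]
    cutpoints: np.ndarray
    state_effects: dict
    age75_effect: float
    loglike: float = float("nan")
    n_obs: int = 0

    def predict(self, prev_state: str, age_ge_75: bool = False) -> np.ndarray:
        """Probability vector over ``levels`` for one previous state."""
        eta = self.state_effects[str(prev_state)] + (
            self.age75_effect if age_ge_75 else 0.0
        )
        cdf = stats.norm.cdf(np.concatenate([self.cutpoints - eta, [np.inf]]))
        return np.diff(np.concatenate([[0.0], cdf]))

    def transition_matrix(self, age_ge_75: bool = False) -> pd.DataFrame:
        """Row-stochastic matrix over living states for one age group."""
        mat = np.vstack([self.predict(s, age_ge_75) for s in self.levels])
        return pd.DataFrame(mat, index=list(self.levels), columns=list(self.levels))


def fit_ordered_probit(
    transitions: pd.DataFrame,
    weights: pd.Series | np.ndarray | None = None,
) -> TransitionModel:
    """Weighted ordered-probit MLE of the one-year cognitive transition.

    ``transitions`` needs ``from_state``, ``to_state`` (living states
    only) and ``age_ge_75``; optional per-row ``weights`` (IPCW). The
    outcome ordering is severity rank. Raises :class:`FittingError` on
    non-convergence, with the optimizer message.
    """
    df = transitions[
        transitions["to_state"].notna()
        & (transitions["to_state"] != SeverityState.DEATH.value)
    ].copy()
    levels = tuple(
        sorted(
            set(df["from_state"]) | set(df["to_state"]), key=severity_rank
        )
    )
    if len(levels) < 2:
        raise FittingError("need >= 2 ordered outcome levels")
    lvl_idx = {s: i for i, s in enumerate(levels)}
    y = df["to_state"].map(lvl_idx).to_numpy()
    from_idx = df["from_state"].map(lvl_idx).to_numpy()
    age75 = df["age_ge_75"].astype(float).to_numpy()
    w = (
        np.asarray(weights, dtype=float)
        if weights is not None
        else np.ones(len(df))
    )
    if w.shape[0] != len(df):
        w = np.asarray(pd.Series(weights).loc[df.index], dtype=float)
    K = len(levels)
    n_eff = K - 1  # state effects for non-reference previous states

    # design: eta = sum_s beta_s 1[from=s, s != ref] + beta75 * age75
    F = np.zeros((len(df), n_eff))
    for j in range(1, K):
        F[:, j - 1] = (from_idx == j).astype(float)

    def unpack(theta):
        beta = theta[:n_eff]
        b75 = theta[n_eff]
        c0 = theta[n_eff + 1]
        cuts = np.concatenate([[c0], c0 + np.cumsum(np.exp(theta[n_eff + 2:]))])
        return beta, b75, cuts

    def negloglike(theta):
        beta, b75, cuts = unpack(theta)
        eta = F @ beta + b75 * age75
        upper = np.concatenate([cuts, [np.inf]])[y] - eta
        lower = np.concatenate([[-np.inf], cuts])[y] - eta
        p = stats.norm.cdf(upper) - stats.norm.cdf(lower)
        return -np.sum(w * np.log(np.clip(p, 1e-300, None)))

    # start: cut-points from marginal outcome frequencies, effects 0
    freq = np.bincount(y, weights=w, minlength=K) / w.sum()
    cum = np.clip(np.cumsum(freq)[:-1], 1e-4, 1 - 1e-4)
    cuts0 = stats.norm.ppf(cum)
    theta0 = np.concatenate(
        [np.zeros(n_eff + 1), [cuts0[0]], np.log(np.maximum(np.diff(cuts0), 1e-3))]
    )
    res = optimize.minimize(negloglike, theta0, method="BFGS",
                            options={"maxiter": 500})
    if not res.success and res.fun > negloglike(theta0):
        raise FittingError(f"ordered probit did not converge: {res.message}")
    beta, b75, cuts = unpack(res.x)
    effects = {levels[0]: 0.0}
    for j in range(1, K):
        effects[levels[j]] = float(beta[j - 1])
    return TransitionModel(
        levels=levels,
        cutpoints=cuts,
        state_effects=effects,
        age75_effect=float(b75),
        loglike=-float(res.fun),
        n_obs=len(df),
    )


# ---------------------------------------------------------------------------
# mortality
# ---------------------------------------------------------------------------

def death_probability(q_age: float, hr: float, rate_based: bool = False):
    """One-year death probability from a life-table probability and an HR.

    Default applies ``1 - exp(-q * HR)`` with the annual death
    *probability* entering the exponent directly. The ``rate_based``
    alternative first converts the probability to a hazard rate:
    ``1 - (1 - q)^HR``. Both accept scalars or arrays.
    """
    q = np.asarray(q_age, dtype=float)
    h = np.asarray(hr, dtype=float)
    if np.any(q < 0) or np.any(q > 1) or np.any(h < 0):
        raise ValueError("require 0 <= q <= 1 and hr >= 0")
    if rate_based:
        out = 1.0 - np.exp(np.log1p(-np.minimum(q, 1 - 1e-15)) * h)
    else:
        out = 1.0 - np.exp(-q * h)
    return out if out.shape else float(out)


@dataclass
class MortalityModel:
    """Weibull PH mortality on the age time-scale.

    ``mode='hr_on_lifetable'`` (base case) applies the fitted hazard
    ratios to life-table probabilities via :func:`death_probability`;
    ``mode='direct_weibull'`` (low-mortality variant) predicts the
    one-year death probability from the fitted Weibull itself.
    """

    shape: float
    scale: float
    hazard_ratios: dict
    reference_state: str
    mode: str = "hr_on_lifetable"

    def hr(self, state) -> float:
        state = str(state)
        if state == self.reference_state or state == SeverityState.MCI.value:
            return 1.0
        return float(self.hazard_ratios[state])

    def annual_death_probability(
        self, age: float, state, life_table: pd.DataFrame | None = None,
        rate_based: bool = False,
    ) -> float:
        if self.mode == "hr_on_lifetable":
            if life_table is None:
                raise ValueError("life table required in hr_on_lifetable mode")
            ages = life_table["age"].to_numpy()
            i = int(np.clip(np.searchsorted(ages, int(age), side="right") - 1,
                            0, len(ages) - 1))
            return death_probability(life_table["q"].to_numpy()[i],
                                     self.hr(state), rate_based=rate_based)
        H = lambda a: (a / self.scale) ** self.shape  # noqa: E731
        return float(1.0 - np.exp(-(H(age + 1.0) - H(age)) * self.hr(state)))


def fit_weibull_mortality(
    episodes: pd.DataFrame,
    reference_state: str = SeverityState.VERY_MILD.value,
    merge_very_mild: bool = False,
    mode: str = "hr_on_lifetable",
) -> MortalityModel:
    """Fit Weibull PH mortality with left truncation at entry age.

    ``episodes`` needs ``entry_age``, ``exit_age``, ``event`` and
    ``state``. Fitting goes through lifelines' Weibull AFT with
    ``entry_col``; AFT coefficients are converted to hazard ratios via
    ``HR = exp(-shape * beta)``. ``merge_very_mild`` pools very mild with
    mild dementia (the low-mortality sensitivity).
    """
    from lifelines import WeibullAFTFitter

    df = episodes.copy()
    if merge_very_mild:
        df.loc[df["state"] == SeverityState.VERY_MILD.value, "state"] = (
            SeverityState.MILD.value
        )
        if reference_state == SeverityState.VERY_MILD.value:
            reference_state = SeverityState.MILD.value
    states = sorted(df["state"].unique(), key=severity_rank)
    if reference_state not in states:
        reference_state = states[0]
    for s in states:
        n_events = int(df.loc[df["state"] == s, "event"].sum())
        if n_events == 0:
            raise FittingError(f"no death events in stratum {s!r}")
    fit_df = pd.DataFrame(
        {
            "entry": df["entry_age"].astype(float),
            "duration": df["exit_age"].astype(float),
            "event": df["event"].astype(int),
        }
    )
    for s in states:
        if s != reference_state:
            fit_df[f"state_{s}"] = (df["state"] == s).astype(float).to_numpy()
    aft = WeibullAFTFitter(penalizer=0.0)
    try:
        aft.fit(fit_df, duration_col="duration", event_col="event",
                entry_col="entry", show_progress=False)
    except Exception as exc:
        raise FittingError(f"Weibull mortality fit failed: {exc}") from exc
    shape = float(np.exp(aft.params_[("rho_", "Intercept")]))
    scale = float(np.exp(aft.params_[("lambda_", "Intercept")]))
    hrs = {reference_state: 1.0}
    for s in states:
        if s != reference_state:
            beta = float(aft.params_[("lambda_", f"state_{s}")])
            hrs[s] = float(np.exp(-shape * beta))
    return MortalityModel(
        shape=shape, scale=scale, hazard_ratios=hrs,
        reference_state=reference_state, mode=mode,
    )


# ---------------------------------------------------------------------------
# costs
# ---------------------------------------------------------------------------

@dataclass
class CostModel:
    """Log-link gamma GLM of annual societal cost on age and severity."""

    params: pd.Series
    dispersion: float
    state_levels: tuple[str, ...]
    reference_state: str

    def predict(self, age, state) -> float | np.ndarray:
        state = np.atleast_1d(np.asarray(state, dtype=object)).astype(str)
        age = np.atleast_1d(np.asarray(age, dtype=float))
        eta = np.full(state.shape, self.params["Intercept"], dtype=float)
        eta += self.params["age"] * age
        for s in self.state_levels:
            key = f"state_{s}"
            if key in self.params.index:
                eta += self.params[key] * (state == s)
        out = np.exp(eta)
        return float(out[0]) if out.size == 1 else out

    def state_effect(self, state: str) -> float:
        """Multiplicative cost ratio of ``state`` vs the reference state."""
        key = f"state_{state}"
        return float(np.exp(self.params[key])) if key in self.params.index else 1.0


def fit_cost_glm(records: pd.DataFrame) -> CostModel:
    """Fit the gamma cost GLM on records with ``age, state, annual_cost``."""
    df = records.copy()
    if (df["annual_cost"] <= 0).any():
        raise ValueError("annual costs must be positive for the gamma GLM")
    levels = tuple(sorted(df["state"].unique(), key=severity_rank))
    ref = levels[0]
    X = pd.DataFrame({"Intercept": 1.0}, index=df.index)
    for s in levels[1:]:
        X[f"state_{s}"] = (df["state"] == s).astype(float)
    X["age"] = df["age"].astype(float)
    res = sm.GLM(
        df["annual_cost"].astype(float), X,
        family=sm.families.Gamma(link=sm.families.links.Log()),
    ).fit()
    return CostModel(
        params=res.params, dispersion=float(res.scale),
        state_levels=levels, reference_state=ref,
    )


# ---------------------------------------------------------------------------
# utilities
# ---------------------------------------------------------------------------

#: EQ-5D-3L value-set bounds.
UTILITY_FLOOR, UTILITY_CEIL = -0.594, 1.0


@dataclass(frozen=True)
class UtilityModel:
    """Linear age-utility with per-state decrements.

    The age-anchored baseline is ``slope * (age - age_offset) +
    intercept`` (slope per year of age); each state's absolute utility is
    the baseline minus its decrement, clamped to the EQ-5D-3L range. The
    same age slope applies in every state. The default decrements of the
    reference input set are calibration choices.
    """

    slope: float = -0.002464
    intercept: float = 0.962679
    decrements: Mapping[str, float] = field(
        default_factory=lambda: {
            "MCI": 0.0,
            "VeryMild": 0.06,
            "Mild": 0.12,
            "Moderate": 0.22,
            "Severe": 0.42,
        }
    )
    age_offset: float = 0.0

    def __post_init__(self):
        dec = dict(self.decrements)
        ranked = [s.value for s in SEVERITY_ORDER if s.value in dec]
        vals = [dec[s] for s in ranked]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("decrements must be non-decreasing with severity")

    def value(self, age: float, state) -> float:
        base = self.slope * (age - self.age_offset) + self.intercept
        dec = self.decrements.get(str(state), 0.0)
        return float(np.clip(base - dec, UTILITY_FLOOR, UTILITY_CEIL))

    def frozen_at(self, age: float) -> "UtilityModel":
        """Age-constant copy anchored at ``age`` (used by the PSA)."""
        return UtilityModel(
            slope=0.0,
            intercept=self.slope * (age - self.age_offset) + self.intercept,
            decrements=dict(self.decrements),
        )


def utility_value(age: float, state, model: UtilityModel | None = None) -> float:
    """Utility of ``state`` at ``age`` under ``model`` (default model)."""
    if not 0 <= age <= 110:
        raise ValueError("age out of supported range [0, 110]")
    model = model if model is not None else UtilityModel()
    return model.value(age, state)
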