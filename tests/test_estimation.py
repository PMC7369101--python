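"""Fitted models: censoring/IPCW, ordered probit, Weibull mortality, costs, utilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from admarkov.estimation import (
    UtilityModel,
    death_probability,
    fit_censoring_model,
    fit_cost_glm,
    fit_ordered_probit,
    fit_weibull_mortality,
    ipcw_weights,
    utility_value,
    FittingError,
)
from admarkov.registry_prep import clean_registry, survival_episodes
from admarkov.states import StagingScheme
from admarkov.synthetic_registry import (
    GeneratorParams,
    MortalitySpec,
    generate_registry,
    simulate_panel,
)


# ---------------------------------------------------------------------------
# censoring + IPCW
# ---------------------------------------------------------------------------

def _intervals(rows):
    df = pd.DataFrame(rows, columns=["person_id", "grid_year", "from_state",
                                     "age", "observed"])
    return df


def test_no_censoring_gives_unit_continuation_and_weights():
    df = _intervals([(i, k, "Mild", 70.0, True)
                     for i in range(20) for k in range(3)])
    model = fit_censoring_model(df)
    p = model.predict_continuation(df["from_state"], df["age"])
    assert np.all(p > 0.999)
    w = ipcw_weights(df, model=model, stabilize=False, truncate_percentile=None)
    assert np.allclose(w, 1.0, atol=1e-3)


def test_censoring_model_matches_two_by_two_logit_oracle():
    """Closed-form 2x2 MLE: intercept and state coefficient are log-odds."""
    rows = (
        [(i, 0, "Mild", 0.0, True) for i in range(80)]
        + [(i, 0, "Mild", 0.0, False) for i in range(80, 100)]
        + [(i, 0, "Severe", 0.0, True) for i in range(100, 150)]
        + [(i, 0, "Severe", 0.0, False) for i in range(150, 200)]
    )
    model = fit_censoring_model(_intervals(rows))
    # hand-computed: logit(80/100) and logit(50/100) - logit(80/100)
    assert model.params["Intercept"] == pytest.approx(np.log(80 / 20), abs=1e-6)
    assert model.params["state_Severe"] == pytest.approx(
        np.log(50 / 50) - np.log(80 / 20), abs=1e-6
    )


def test_ipcw_weights_are_inverse_cumulative_products():
    df = _intervals([(1, k, "Mild", 70.0, True) for k in range(4)])
    w = ipcw_weights(df, continuation=np.full(4, 0.8),
                     stabilize=False, truncate_percentile=None)
    assert np.allclose(w.to_numpy(), [0.8 ** -(k + 1) for k in range(4)])
    assert (w >= 1.0).all()


def test_ipcw_rejects_nonpositive_probabilities():
    df = _intervals([(1, 0, "Mild", 70.0, True)])
    with pytest.raises(ValueError):
        ipcw_weights(df, continuation=np.array([0.0]))


# ---------------------------------------------------------------------------
# ordered probit
# ---------------------------------------------------------------------------

def test_pure_self_transitions_give_identity_matrix():
    df = pd.DataFrame({
        "from_state": ["Mild"] * 60 + ["Moderate"] * 60 + ["Severe"] * 60,
        "to_state": ["Mild"] * 60 + ["Moderate"] * 60 + ["Severe"] * 60,
        "age_ge_75": [False] * 180,
    })
    tm = fit_ordered_probit(df)
    M = tm.transition_matrix(False).to_numpy()
    assert np.all(np.diag(M) > 0.99)


def test_predicted_rows_sum_to_one_for_all_groups():
    rng = np.random.default_rng(0)
    names = np.array(["Mild", "Moderate", "Severe"])
    df = pd.DataFrame({
        "from_state": rng.choice(names, 500),
        "to_state": rng.choice(names, 500),
        "age_ge_75": rng.uniform(size=500) < 0.5,
    })
    tm = fit_ordered_probit(df)
    for a75 in (False, True):
        M = tm.transition_matrix(a75).to_numpy()
        assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)


def test_unweighted_fit_matches_statsmodels_ordered_model():
    """Dual route: our weighted MLE at unit weights vs statsmodels probit."""
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    rng = np.random.default_rng(5)
    n = 2000
    prev = rng.choice(["Mild", "Moderate", "Severe"], size=n)
    a75 = rng.uniform(size=n) < 0.4
    eta = np.array(
        [{"Mild": 0, "Moderate": 1.2, "Severe": 2.4}[s] for s in prev]
    ) + 0.3 * a75
    y = np.searchsorted([0.7, 2.2], eta + rng.standard_normal(n))
    names = np.array(["Mild", "Moderate", "Severe"])
    df = pd.DataFrame({"from_state": prev, "to_state": names[y],
                       "age_ge_75": a75})
    tm = fit_ordered_probit(df)
    endog = pd.Series(pd.Categorical.from_codes(
        y, categories=["Mild", "Moderate", "Severe"], ordered=True))
    exog = pd.DataFrame({
        "mod": (prev == "Moderate").astype(float),
        "sev": (prev == "Severe").astype(float),
        "a75": a75.astype(float),
    })
    ref = OrderedModel(endog, exog, distr="probit").fit(method="bfgs",
                                                        disp=False)
    assert tm.state_effects["Moderate"] == pytest.approx(ref.params.iloc[0],
                                                         abs=2e-3)
    assert tm.state_effects["Severe"] == pytest.approx(ref.params.iloc[1],
                                                       abs=2e-3)
    assert tm.age75_effect == pytest.approx(ref.params.iloc[2], abs=2e-3)
    cuts_ref = [ref.params.iloc[3], ref.params.iloc[3] + np.exp(ref.params.iloc[4])]
    assert np.allclose(tm.cutpoints, cuts_ref, atol=2e-3)


def test_ordered_probit_needs_two_levels():
    df = pd.DataFrame({"from_state": ["Mild"] * 5, "to_state": ["Mild"] * 5,
                       "age_ge_75": [False] * 5})
    with pytest.raises(FittingError):
        fit_ordered_probit(df)


# ---------------------------------------------------------------------------
# mortality
# ---------------------------------------------------------------------------

def _mortality_episodes(seed, hrs, shape=7.0, scale=88.0, n=2000):
    params = GeneratorParams(
        n_individuals=n, seed=seed, dropout_intercept=-30.0,
        visit_jitter_sd_months=0.0,
        mortality=MortalitySpec(hazard_ratios=hrs, weibull_shape=shape,
                                weibull_scale=scale),
    )
    clean, _ = clean_registry(generate_registry(params))
    return survival_episodes(clean, StagingScheme.THREE_LEVEL)


def test_equal_hazards_give_unit_hazard_ratios():
    eps = _mortality_episodes(
        1, {"Mild": 1.0, "Moderate": 1.0, "Severe": 1.0})
    mm = fit_weibull_mortality(eps, reference_state="Mild")
    assert mm.hazard_ratios["Moderate"] == pytest.approx(1.0, abs=0.2)
    assert mm.hazard_ratios["Severe"] == pytest.approx(1.0, abs=0.25)


def test_exponential_special_case_gives_flat_fitted_hazard():
    # Weibull shape 1 on the age scale = constant hazard (exponential).
    # Episodes at the life-table terminal age (certain death) are excluded:
    # they are an artefact of the table's closure, not of the hazard law.
    eps = _mortality_episodes(
        2, {"Mild": 1.0, "Moderate": 1.0, "Severe": 1.0}, shape=1.0, scale=25.0,
        n=3000,
    )
    eps = eps[eps["exit_age"] < 105.0]
    mm = fit_weibull_mortality(eps, reference_state="Mild")

    def hazard(age):
        return mm.shape / mm.scale * (age / mm.scale) ** (mm.shape - 1)

    # shape ~ 1 means the fitted hazard barely varies across the age window
    assert hazard(85.0) / hazard(65.0) == pytest.approx(1.0, abs=0.2)
    assert hazard(75.0) == pytest.approx(1 / 25.0, rel=0.15)


def test_missing_events_in_stratum_raises_named_error():
    eps = pd.DataFrame({
        "entry_age": [70.0, 71.0, 70.0],
        "exit_age": [71.0, 72.0, 71.0],
        "event": [True, True, False],
        "state": ["Mild", "Mild", "Severe"],
    })
    with pytest.raises(FittingError, match="Severe"):
        fit_weibull_mortality(eps, reference_state="Mild")


@pytest.mark.parametrize(
    "q, hr, expected",
    [(0.01, 1.0, 0.00995017), (0.02, 2.0, 0.039211), (0.5, 0.0, 0.0)],
)
def test_death_probability_printed_formula(q, hr, expected):
    assert death_probability(q, hr) == pytest.approx(expected, abs=5e-7)


def test_death_probability_rate_based_alternative():
    assert death_probability(0.02, 2.0, rate_based=True) == pytest.approx(
        1.0 - 0.98 ** 2
    )


@settings(derandomize=True, max_examples=60)
@given(
    q=st.floats(min_value=0.0, max_value=1.0),
    hr=st.floats(min_value=0.0, max_value=10.0),
)
def test_death_probability_bounds_and_monotonicity(q, hr):
    p = death_probability(q, hr)
    assert 0.0 <= p <= 1.0
    assert death_probability(min(q + 0.05, 1.0), hr) >= p - 1e-12
    assert death_probability(q, hr + 0.5) >= p - 1e-12


def test_death_probability_rejects_negative_inputs():
    with pytest.raises(ValueError):
        death_probability(-0.1, 1.0)
    with pytest.raises(ValueError):
        death_probability(0.1, -1.0)


# ---------------------------------------------------------------------------
# costs
# ---------------------------------------------------------------------------

def test_cost_glm_is_age_flat_when_generated_flat():
    params = GeneratorParams(n_individuals=1500, seed=5, cost_age_coef=0.0)
    panel = simulate_panel(params)
    cm = fit_cost_glm(panel[["age", "state", "annual_cost"]])
    assert cm.params["age"] == pytest.approx(0.0, abs=5e-3)
    ratio = cm.predict(90.0, "Mild") / cm.predict(60.0, "Mild")
    assert ratio == pytest.approx(1.0, abs=0.2)


def test_cost_glm_calibration_at_mean_covariates():
    """Gamma/log-link: prediction near sample-mean covariates tracks mean cost."""
    params = GeneratorParams(n_individuals=1500, seed=6)
    panel = simulate_panel(params)
    one = panel[panel["state"] == "Moderate"]
    cm = fit_cost_glm(panel[["age", "state", "annual_cost"]])
    pred = cm.predict(one["age"].mean(), "Moderate")
    assert pred == pytest.approx(one["annual_cost"].mean(), rel=0.05)


def test_cost_glm_rejects_nonpositive_costs():
    df = pd.DataFrame({"age": [70.0, 71.0], "state": ["Mild", "Mild"],
                       "annual_cost": [1000.0, 0.0]})
    with pytest.raises(ValueError):
        fit_cost_glm(df)


def test_cost_predictions_positive_over_engine_range():
    params = GeneratorParams(n_individuals=800, seed=7)
    panel = simulate_panel(params)
    cm = fit_cost_glm(panel[["age", "state", "annual_cost"]])
    for age in (60, 80, 100):
        for s in ("Mild", "Moderate", "Severe"):
            assert cm.predict(float(age), s) > 0


# ---------------------------------------------------------------------------
# utilities
# ---------------------------------------------------------------------------

def test_utility_linear_formula_values():
    m = UtilityModel(decrements={"MCI": 0.0})
    assert utility_value(0, "MCI", m) == pytest.approx(0.962679)
    assert utility_value(60, "MCI", m) == pytest.approx(
        -0.002464 * 60 + 0.962679
    )


def test_utility_non_increasing_with_severity_and_bounded():
    m = UtilityModel()
    for age in (60, 75, 90, 110):
        vals = [m.value(age, s) for s in ("MCI", "Mild", "Moderate", "Severe")]
        assert vals == sorted(vals, reverse=True)
        assert all(-0.594 <= v <= 1.0 for v in vals)


def test_utility_rejects_unordered_decrements():
    with pytest.raises(ValueError):
        UtilityModel(decrements={"Mild": 0.3, "Moderate": 0.1, "Severe": 0.4})


def test_frozen_utility_is_age_constant():
    m = UtilityModel()
    f = m.frozen_at(71.0)
    assert f.value(60, "Mild") == f.value(90, "Mild")
    assert f.value(71, "Mild") == pytest.approx(m.value(71, "Mild"))
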