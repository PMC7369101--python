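"""Severity staging, registry cleaning, annualization and transition building."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from admarkov.states import SeverityState, StagingScheme, classify_severity
from admarkov.registry_prep import (
    annualize,
    build_transitions,
    clean_registry,
    prepare_transitions,
    round_half_up,
)
from admarkov.synthetic_registry import (
    CorruptionSpec,
    GeneratorParams,
    generate_registry,
)

D = pd.Timestamp


@pytest.mark.parametrize(
    "mmse, scheme, expected",
    [
        (21, StagingScheme.THREE_LEVEL, SeverityState.MILD),
        (20, StagingScheme.THREE_LEVEL, SeverityState.MODERATE),
        (10, StagingScheme.THREE_LEVEL, SeverityState.MODERATE),
        (9, StagingScheme.THREE_LEVEL, SeverityState.SEVERE),
        (30, StagingScheme.THREE_LEVEL, SeverityState.MILD),
        (0, StagingScheme.THREE_LEVEL, SeverityState.SEVERE),
        (27, StagingScheme.FOUR_LEVEL, SeverityState.VERY_MILD),
        (26, StagingScheme.FOUR_LEVEL, SeverityState.MILD),
        (30, StagingScheme.FOUR_LEVEL, SeverityState.VERY_MILD),
        (20, StagingScheme.FOUR_LEVEL, SeverityState.MODERATE),
    ],
)
def test_mmse_staging_boundaries(mmse, scheme, expected):
    assert classify_severity(mmse, scheme) is expected


@pytest.mark.parametrize("mmse", [-1, 31, 100])
def test_mmse_staging_rejects_out_of_range(mmse):
    with pytest.raises(ValueError):
        classify_severity(mmse)


@settings(derandomize=True, max_examples=62)
@given(
    mmse=st.integers(min_value=0, max_value=30),
    scheme=st.sampled_from(list(StagingScheme)),
)
def test_staging_total_and_severity_only(mmse, scheme):
    """Staging is a total function of MMSE yielding a living dementia state."""
    state = classify_severity(mmse, scheme)
    assert state in {
        SeverityState.VERY_MILD, SeverityState.MILD,
        SeverityState.MODERATE, SeverityState.SEVERE,
    }
    if scheme is StagingScheme.THREE_LEVEL:
        assert state is not SeverityState.VERY_MILD


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def _tbl(rows):
    return pd.DataFrame(
        rows, columns=["person_id", "visit_date", "mmse", "death_date"]
    )


def test_short_interval_rule_excludes_visit_within_four_months():
    df = _tbl([
        (1, D("2015-01-01"), 28, pd.NaT),
        (1, D("2015-04-01"), 27, pd.NaT),   # 3 months after baseline
        (1, D("2016-01-01"), 26, pd.NaT),
    ])
    clean, rep = clean_registry(df)
    assert rep.counts["short_interval"] == 1
    assert len(clean) == 2
    assert rep.kept_rows + rep.total_excluded() == rep.input_rows


def test_clean_empty_table():
    clean, rep = clean_registry(pd.DataFrame(
        columns=["person_id", "visit_date", "mmse", "death_date"]))
    assert clean.empty
    assert rep.total_excluded() == 0 and rep.kept_rows == 0


def test_clean_collects_unparseable_dates_without_crashing():
    df = _tbl([
        (1, "not-a-date", 25, pd.NaT),
        (1, D("2015-01-01"), 25, pd.NaT),
    ])
    clean, rep = clean_registry(df)
    assert rep.counts["invalid_date"] == 1
    assert len(clean) == 1


def test_after_death_duplicate_and_no_mmse_rules():
    death = D("2016-06-01")
    df = _tbl([
        (1, D("2015-01-01"), 25, death),
        (1, D("2016-01-01"), 22, death),
        (1, D("2016-01-01"), 22, death),    # duplicate date
        (1, D("2016-09-01"), 20, death),    # after death
        (2, D("2015-01-01"), None, pd.NaT),  # person without any MMSE
    ])
    clean, rep = clean_registry(df)
    assert rep.counts["duplicate_date"] == 1
    assert rep.counts["after_death"] == 1
    assert rep.counts["no_mmse"] == 1
    assert set(clean["person_id"]) == {1}


def test_baseline_rules_with_designated_baseline():
    df = _tbl([
        (1, D("2015-06-01"), 25, pd.NaT),
        (1, D("2015-01-01"), 27, pd.NaT),   # before the designated baseline
        (2, D("2015-01-01"), 24, pd.NaT),   # no baseline at all
    ])
    df["is_baseline"] = [True, False, False]
    clean, rep = clean_registry(df)
    assert rep.counts["before_baseline"] == 1
    assert rep.counts["no_baseline"] == 1
    assert set(clean["person_id"]) == {1}


def test_clean_is_idempotent_on_generated_corrupted_registry():
    params = GeneratorParams(
        n_individuals=200, seed=3,
        corruption=CorruptionSpec(short_interval=5, duplicate_date=5,
                                  after_death=5, missing_mmse=5),
    )
    reg = generate_registry(params)
    clean1, rep1 = clean_registry(reg)
    clean2, rep2 = clean_registry(clean1)
    assert rep2.total_excluded() == 0
    assert len(clean2) == len(clean1)


def test_injected_defect_counts_match_exclusion_report():
    """Each injected defect class is recovered by its cleaning rule."""
    spec = CorruptionSpec(short_interval=7, duplicate_date=6,
                          after_death=5, missing_mmse=4)
    params = GeneratorParams(n_individuals=300, seed=9, corruption=spec)
    reg = generate_registry(params)
    _, rep = clean_registry(reg)
    assert rep.counts["short_interval"] == spec.short_interval
    assert rep.counts["duplicate_date"] == spec.duplicate_date
    assert rep.counts["after_death"] == spec.after_death
    # missing-MMSE is a person-level rule: all of the person's rows go
    n_rows = (
        reg.groupby("person_id")["mmse"].apply(lambda s: s.isna().all()).sum()
    )
    assert n_rows == spec.missing_mmse
    assert rep.counts["no_mmse"] >= spec.missing_mmse


# ---------------------------------------------------------------------------
# annualization
# ---------------------------------------------------------------------------

def test_linear_interpolation_on_annual_grid():
    grid = annualize([(D("2015-01-01"), 28), (D("2017-01-01"), 20)],
                     D("2015-01-01"))
    vals = dict(grid)
    assert vals[0] == 28
    assert vals[1] == pytest.approx(24.0, abs=0.05)  # midpoint of 28 -> 20
    assert vals[2] == 20


def test_visit_on_anniversary_is_reproduced_exactly():
    grid = annualize(
        [(D("2015-03-10"), 29), (D("2016-03-10"), 26), (D("2017-03-10"), 21)],
        D("2015-03-10"),
    )
    assert dict(grid) == {0: 29.0, 1: 26.0, 2: 21.0}


def test_forward_extrapolation_limited_to_three_months():
    # last visit 2 months before the anniversary: grid point covered
    g1 = annualize([(D("2015-01-01"), 28), (D("2015-11-01"), 25)],
                   D("2015-01-01"))
    assert 1 in dict(g1)
    # last visit 4 months before the anniversary: grid point absent
    g2 = annualize([(D("2015-01-01"), 28), (D("2015-09-01"), 25)],
                   D("2015-01-01"))
    assert 1 not in dict(g2)


def test_single_visit_yields_baseline_point_only():
    grid = annualize([(D("2015-01-01"), 23)], D("2015-01-01"))
    assert grid == [(0, 23.0)]


def test_annualized_values_clamped_to_mmse_range():
    # steep decline extrapolates below zero without clamping
    grid = annualize([(D("2015-01-01"), 6), (D("2015-12-15"), 1)],
                     D("2015-01-01"))
    assert all(0.0 <= v <= 30.0 for _, v in grid)


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------

def _grids(entries):
    return {
        pid: {"grid": g, "anchor": D("2015-01-01"),
              "baseline_age": age, "death_date": death}
        for pid, (g, age, death) in entries.items()
    }


def test_consecutive_grid_points_become_transitions():
    grids = _grids({1: ([(0, 25.0), (1, 24.0), (2, 15.0)], 70.0, pd.NaT)})
    tr = build_transitions(grids)
    obs = tr[tr["observed"]]
    assert list(zip(obs["from_state"], obs["to_state"]))[:2] == [
        ("Mild", "Mild"), ("Mild", "Moderate"),
    ]
    # no death within a year of the last point: censoring record instead
    cens = tr[~tr["observed"]]
    assert len(cens) == 1 and cens["from_state"].iloc[0] == "Moderate"


def test_death_within_year_after_grid_point_becomes_death_transition():
    grids = _grids({1: ([(0, 25.0), (1, 24.0), (2, 15.0)], 70.0,
                        D("2017-07-01"))})  # 6 months after grid year 2
    tr = build_transitions(grids)
    last = tr[tr["grid_year"] == 2].iloc[0]
    assert last["to_state"] == "Death" and last["observed"]


def test_death_long_after_last_point_is_censoring_not_death():
    grids = _grids({1: ([(0, 25.0)], 70.0, D("2016-06-01"))})  # 17 months on
    tr = build_transitions(grids)
    assert not tr["observed"].iloc[0]
    assert tr["to_state"].isna().iloc[0]


def test_fractional_mmse_rounds_half_up_before_staging():
    assert round_half_up(20.5) == 21
    grids = _grids({1: ([(0, 20.5), (1, 20.49)], 70.0, pd.NaT)})
    tr = build_transitions(grids)
    assert tr["from_state"].iloc[0] == "Mild"       # 20.5 -> 21 -> Mild
    obs = tr[tr["observed"]].iloc[0]
    assert obs["to_state"] == "Moderate"            # 20.49 -> 20 -> Moderate


def test_transition_count_identity_on_clean_cohort():
    """Transitions = sum over persons of (grid points - 1 + death events)."""
    params = GeneratorParams(n_individuals=400, seed=21,
                             dropout_intercept=-30.0,
                             visit_jitter_sd_months=0.0)
    reg = generate_registry(params)
    clean, _ = clean_registry(reg)
    tr = prepare_transitions(clean)
    observed = tr[tr["observed"]]
    expected = 0
    for pid, grp in clean.groupby("person_id"):
        grp = grp.sort_values("visit_date")
        grid = annualize(
            list(zip(grp["visit_date"], grp["mmse"].astype(float))),
            grp["visit_date"].iloc[0],
        )
        death = grp["death_date"].iloc[0]
        anchor = grp["visit_date"].iloc[0]
        if not pd.isna(death):
            grid = [
                (k, v) for k, v in grid
                if anchor + pd.DateOffset(years=k) <= death
            ]
        if not grid:
            continue
        expected += len(grid) - 1
        k_last = max(k for k, _ in grid)
        if not pd.isna(death) and death <= (
            anchor + pd.DateOffset(years=k_last) + pd.DateOffset(years=1)
        ):
            expected += 1
    assert len(observed) == expected


def test_transition_counts_decline_with_follow_up_year(small_registry):
    reg, _ = small_registry
    clean, _ = clean_registry(reg)
    tr = prepare_transitions(clean)
    counts = tr[tr["observed"]].groupby("grid_year").size()
    counts = counts[counts.index < 6]
    assert (counts.diff().dropna() < 0).all()
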