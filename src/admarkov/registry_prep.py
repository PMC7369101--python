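"""Registry cleaning, severity staging and annualized transition pairs.

Raw registry visits are cleaned under a fixed, documented rule order,
MMSE is linearly inter-/extrapolated onto an annual grid anchored at each
person's baseline visit, and consecutive grid points become one-year
state-to-state transition pairs. A death within the year after a grid
point becomes a transition to Death; otherwise the person is censored one
year after the last available MMSE status, producing the censoring
records the IPCW stage consumes.

Cleaning rule order (record-level first, person-level last); the order
affects only the attribution of exclusions, not the kept set:

1. ``invalid_date`` - missing/unparseable visit date
2. ``after_death`` - follow-up dated after the death date
3. ``duplicate_date`` - same person, same date (first kept)
4. ``before_baseline`` - follow-up dated before the designated baseline
   (only when an ``is_baseline`` column designates baselines)
5. ``no_baseline`` - person without a baseline assessment
6. ``short_interval`` - < 4 months after the previous *kept* visit
7. ``no_mmse`` - person without any MMSE assessment
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .states import SeverityState, StagingScheme, classify_severity

_DAYS_PER_YEAR = 365.25
_EXTRAPOLATION_LIMIT = pd.DateOffset(months=3)
_MIN_INTERVAL = pd.DateOffset(months=4)

RULE_ORDER = (
    "invalid_date",
    "after_death",
    "duplicate_date",
    "before_baseline",
    "no_baseline",
    "short_interval",
    "no_mmse",
)


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties away from zero-half (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


@dataclass
class ExclusionReport:
    """Tally of records excluded per cleaning rule."""

    input_rows: int = 0
    kept_rows: int = 0
    counts: dict = field(default_factory=lambda: {r: 0 for r in RULE_ORDER})

    def total_excluded(self) -> int:
        return sum(self.counts.values())

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def clean_registry(df: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the cleaning rules in their fixed order.

    Returns the kept records (sorted by person and date) and an
    :class:`ExclusionReport` whose counts sum with the kept rows to the
    input rows. Unparseable dates are collected as exclusions, never
    raised. Idempotent: re-cleaning a cleaned table excludes nothing.
    """
    report = ExclusionReport(input_rows=len(df))
    if df.empty:
        return df.copy(), report
    df = df.copy().reset_index(drop=True)
    df["visit_date"] = pd.to_datetime(df["visit_date"], errors="coerce")
    if "death_date" in df.columns:
        df["death_date"] = pd.to_datetime(df["death_date"], errors="coerce")
    else:
        df["death_date"] = pd.NaT

    bad = df["visit_date"].isna()
    report.counts["invalid_date"] = int(bad.sum())
    df = df[~bad]

    after = df["death_date"].notna() & (df["visit_date"] > df["death_date"])
    report.counts["after_death"] = int(after.sum())
    df = df[~after]

    df = df.sort_values(["person_id", "visit_date"], kind="stable")
    dup = df.duplicated(subset=["person_id", "visit_date"], keep="first")
    report.counts["duplicate_date"] = int(dup.sum())
    df = df[~dup]

    if "is_baseline" in df.columns:
        base_dates = (
            df[df["is_baseline"].astype(bool)]
            .groupby("person_id")["visit_date"]
            .min()
        )
        df = df.merge(
            base_dates.rename("baseline_date"), on="person_id", how="left"
        )
        no_base = df["baseline_date"].isna()
        before = df["baseline_date"].notna() & (
            df["visit_date"] < df["baseline_date"]
        )
        report.counts["before_baseline"] = int(before.sum())
        report.counts["no_baseline"] = int(no_base.sum())
        df = df[~(no_base | before)].drop(columns=["baseline_date"])
        df = df.sort_values(["person_id", "visit_date"], kind="stable")

    # short-interval rule: compare with the previous *kept* visit
    keep_mask = np.ones(len(df), dtype=bool)
    dates = df["visit_date"].to_numpy()
    pids = df["person_id"].to_numpy()
    prev_kept: dict = {}
    for i in range(len(df)):
        pid = pids[i]
        d = pd.Timestamp(dates[i])
        if pid in prev_kept and d < prev_kept[pid] + _MIN_INTERVAL:
            keep_mask[i] = False
        else:
            prev_kept[pid] = d
    report.counts["short_interval"] = int((~keep_mask).sum())
    df = df[keep_mask]

    has_mmse = df.groupby("person_id")["mmse"].transform(lambda s: s.notna().any())
    report.counts["no_mmse"] = int((~has_mmse).sum())
    df = df[has_mmse]

    df = df.reset_index(drop=True)
    report.kept_rows = len(df)
    return df, report


def annualize(
    visits: list[tuple[pd.Timestamp, float]], anchor: pd.Timestamp
) -> list[tuple[int, float]]:
    """Inter-/extrapolate MMSE onto the annual grid anchored at baseline.

    Grid point k lives at ``anchor + k years``. Between visits, MMSE is
    linearly interpolated in days; beyond the last visit, linear
    extrapolation from the last two visits covers at most 3 months past
    the last visit. No backward extrapolation before the first visit.
    Values are clamped to [0, 30] and kept fractional (rounding is the
    staging step's job). A single visit yields only a grid point that
    coincides with it.
    """
    vis = sorted(
        ((pd.Timestamp(d), float(m)) for d, m in visits if not pd.isna(m)),
        key=lambda t: t[0],
    )
    if not vis:
        return []
    anchor = pd.Timestamp(anchor)
    last_date = vis[-1][0]
    limit = last_date + _EXTRAPOLATION_LIMIT
    dates = [d for d, _ in vis]
    values = [m for _, m in vis]
    out: list[tuple[int, float]] = []
    k = 0
    while True:
        g = anchor + pd.DateOffset(years=k)
        if g > limit:
            break
        if g < dates[0]:
            k += 1
            continue
        if g <= last_date:
            j = int(np.searchsorted(np.array(dates, dtype="datetime64[ns]"), np.datetime64(g), side="left"))
            if j < len(dates) and dates[j] == g:
                val = values[j]
            else:
                d0, d1 = dates[j - 1], dates[j]
                w = (g - d0).days / (d1 - d0).days
                val = values[j - 1] + w * (values[j] - values[j - 1])
        else:
            if len(vis) < 2:
                break  # single visit: no extrapolation possible
            d0, d1 = dates[-2], dates[-1]
            slope = (values[-1] - values[-2]) / (d1 - d0).days
            val = values[-1] + slope * (g - d1).days
        out.append((k, float(np.clip(val, 0.0, 30.0))))
        k += 1
    return out


def build_transitions(
    grids: dict,
    scheme: StagingScheme = StagingScheme.THREE_LEVEL,
) -> pd.DataFrame:
    """Turn per-person annual MMSE grids into one-year transition records.

    Parameters
    ----------
    grids : dict
        ``person_id -> {"grid": [(k, mmse)], "anchor": Timestamp,
        "baseline_age": float, "death_date": Timestamp or NaT}``.
    scheme : StagingScheme
        Severity staging applied to half-up-rounded grid MMSE.

    Returns
    -------
    DataFrame with one row per person-interval: ``person_id, grid_year,
    from_state, to_state, age, age_ge_75, observed, weight``. ``to_state``
    is NaN and ``observed`` False for the censoring interval one year
    after the last available MMSE (only when death does not occur within
    that year).
    """
    rows = []
    for pid, info in grids.items():
        grid = sorted(info["grid"])
        if not grid:
            continue
        anchor = pd.Timestamp(info["anchor"])
        death = info.get("death_date", pd.NaT)
        base_age = float(info["baseline_age"])
        # grid points after death are artefacts of extrapolation; drop them
        if not pd.isna(death):
            grid = [
                (k, v) for k, v in grid if anchor + pd.DateOffset(years=k) <= death
            ]
        if not grid:
            continue
        states = {
            k: classify_severity(round_half_up(v), scheme) for k, v in grid
        }
        ks = [k for k, _ in grid]
        for k in ks[:-1]:
            if k + 1 not in states:
                continue
            age = base_age + k
            rows.append(
                (pid, k, states[k].value, states[k + 1].value, age, age >= 75, True)
            )
        k_last = ks[-1]
        age = base_age + k_last
        g_last = anchor + pd.DateOffset(years=k_last)
        if not pd.isna(death) and death <= g_last + pd.DateOffset(years=1):
            rows.append(
                (pid, k_last, states[k_last].value, SeverityState.DEATH.value,
                 age, age >= 75, True)
            )
        else:
            rows.append(
                (pid, k_last, states[k_last].value, None, age, age >= 75, False)
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "person_id", "grid_year", "from_state", "to_state",
            "age", "age_ge_75", "observed",
        ],
    )
    out["weight"] = 1.0
    return out


def prepare_transitions(
    clean_df: pd.DataFrame, scheme: StagingScheme = StagingScheme.THREE_LEVEL
) -> pd.DataFrame:
    """Annualize each person of a cleaned registry and build transitions."""
    grids = {}
    for pid, grp in clean_df.groupby("person_id", sort=True):
        grp = grp.sort_values("visit_date")
        visits = list(zip(grp["visit_date"], grp["mmse"].astype(float)))
        anchor = grp["visit_date"].iloc[0]
        grid = annualize(visits, anchor)
        if not grid:
            continue
        grids[pid] = {
            "grid": grid,
            "anchor": anchor,
            "baseline_age": float(grp["age_at_visit"].iloc[0]),
            "death_date": grp["death_date"].iloc[0],
        }
    return build_transitions(grids, scheme)


def survival_episodes(clean_df: pd.DataFrame,
                      scheme: StagingScheme = StagingScheme.FOUR_LEVEL,
                      min_age: float = 60.0) -> pd.DataFrame:
    """Left-truncated person-year survival episodes on the age time-scale.

    For mortality estimation: each observed person-year contributes one
    episode (entry age, exit age, event flag, severity at entry). Follow-up
    is censored one year after the last available MMSE. Episodes starting
    below ``min_age`` are omitted.
    """
    transitions = prepare_transitions(clean_df, scheme)
    death_dates = clean_df.groupby("person_id")["death_date"].first()
    anchors = clean_df.groupby("person_id")["visit_date"].min()
    rows = []
    for r in transitions.itertuples():
        if r.age < min_age:
            continue
        if r.to_state == SeverityState.DEATH.value:
            death = death_dates.loc[r.person_id]
            anchor = anchors.loc[r.person_id]
            exit_age = r.age + min(
                max((death - (anchor + pd.DateOffset(years=r.grid_year))).days
                    / _DAYS_PER_YEAR, 1e-6), 1.0)
            event = True
        else:
            exit_age = r.age + 1.0
            event = False
        rows.append((r.person_id, r.age, exit_age, event, r.from_state))
    return pd.DataFrame(
        rows, columns=["person_id", "entry_age", "exit_age", "event", "state"]
    )
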