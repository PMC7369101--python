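"""Cognitive severity states and MMSE staging.

The disease continuum is discretized into an ordered set of health states.
Severity is staged from the Mini-Mental State Examination (MMSE, 0-30,
higher = better cognition):

* 3-level scheme: Mild 21-30, Moderate 10-20, Severe 0-9.
* 4-level scheme: Very mild 27-30 split out of Mild (21-26); used only for
  mortality estimation, where very mild dementia is the reference level.

``MCI`` (mild cognitive impairment due to AD) is the cohort entry state of
the simulation model and is never produced by MMSE staging of dementia
registry records. ``DEATH`` is absorbing.
"""

from __future__ import annotations

from enum import Enum


class SeverityState(str, Enum):
    MCI = "MCI"
    VERY_MILD = "VeryMild"
    MILD = "Mild"
    MODERATE = "Moderate"
    SEVERE = "Severe"
    DEATH = "Death"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class StagingScheme(str, Enum):
    THREE_LEVEL = "3level"
    FOUR_LEVEL = "4level"


#: Ordered living states of the cohort engine (best to worst).
ENGINE_LIVING_STATES = (
    SeverityState.MCI,
    SeverityState.MILD,
    SeverityState.MODERATE,
    SeverityState.SEVERE,
)

#: Full engine state space, Death last.
ENGINE_STATES = ENGINE_LIVING_STATES + (SeverityState.DEATH,)

#: Dementia severity levels produced by 3-level staging, best to worst.
DEMENTIA_STATES_3 = (SeverityState.MILD, SeverityState.MODERATE, SeverityState.SEVERE)

#: Dementia severity levels under the 4-level scheme, best to worst.
DEMENTIA_STATES_4 = (
    SeverityState.VERY_MILD,
    SeverityState.MILD,
    SeverityState.MODERATE,
    SeverityState.SEVERE,
)

#: Global severity ordering used wherever states must be ranked.
SEVERITY_ORDER = (
    SeverityState.MCI,
    SeverityState.VERY_MILD,
    SeverityState.MILD,
    SeverityState.MODERATE,
    SeverityState.SEVERE,
    SeverityState.DEATH,
)


def severity_rank(state: SeverityState) -> int:
    """Rank of ``state`` in the global severity ordering (MCI lowest)."""
    return SEVERITY_ORDER.index(SeverityState(state))


def classify_severity(
    mmse: int, scheme: StagingScheme = StagingScheme.THREE_LEVEL
) -> SeverityState:
    """Stage an MMSE score into a dementia severity state.

    Parameters
    ----------
    mmse : int
        Integer MMSE score in [0, 30].
    scheme : StagingScheme
        3-level (Mild/Moderate/Severe) or 4-level (Very mild split out).

    Returns
    -------
    SeverityState
    """
    mmse = int(mmse)
    if not 0 <= mmse <= 30:
        raise ValueError(f"MMSE must be in [0, 30], got {mmse}")
    scheme = StagingScheme(scheme)
    if mmse >= 21:
        if scheme is StagingScheme.FOUR_LEVEL and mmse >= 27:
            return SeverityState.VERY_MILD
        return SeverityState.MILD
    if mmse >= 10:
        return SeverityState.MODERATE
    return SeverityState.SEVERE
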