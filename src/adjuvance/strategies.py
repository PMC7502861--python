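"""Treatment strategies: CAPOX/FOLFOX for 3 or 6 months.

Each strategy arm combines a regimen (cycle structure and drug cost), a
composed treatment-effect hazard ratio, an adverse-event profile and an
arm-specific utility schedule.  The 6-month regimens carry an HR for
recurrence of 0.73 versus no adjuvant treatment; the 3-month regimens
multiply that by a drug-specific HR for 3 versus 6 months of treatment
(1.0 for CAPOX, 1.4 for FOLFOX, from the pooled IDEA stage II analysis),
so 3 months of FOLFOX (0.73 x 1.4 = 1.022) is essentially equivalent to
no adjuvant treatment at all.

Utilities are period averages from the SCOT trial, reported separately
for the two durations; after a recurrence the utility drops to 0.45 for
60 months, after which the patient counts as a cancer survivor at 0.90.
The arm-specific schedule is taken to absorb toxicity effects, so no
separate adverse-event disutility is applied; adverse events enter as a
one-off expected cost per treated patient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .cohort_engine import HealthState

__all__ = [
    "Regimen",
    "TreatmentEffect",
    "AdverseEvent",
    "AdverseEventProfile",
    "UtilityPeriod",
    "UtilitySchedule",
    "REGIMENS",
    "TREATMENT_EFFECTS",
    "DEFAULT_AE_PROFILE",
    "DEFAULT_UTILITY_SCHEDULE",
    "effective_hr",
    "expected_ae_cost",
    "chemo_window",
    "utility_at",
]

DRUGS = ("CAPOX", "FOLFOX")
DURATIONS = (3, 6)


def _check_duration(duration: int) -> None:
    if duration not in DURATIONS:
        raise ValueError(f"treatment duration must be 3 or 6 months, got {duration}")


@dataclass(frozen=True)
class Regimen:
    """One drug/duration arm's cycle structure and full-course drug cost (2018 EUR)."""

    drug: str
    duration: int
    n_cycles: int
    cycle_length_weeks: int
    full_regimen_cost: float
    quit_proportion: float = 0.07
    body_surface_reference: float = 1.7  # m^2, metadata only

    def __post_init__(self) -> None:
        _check_duration(self.duration)
        if self.drug not in DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}")


#: printed full-regimen drug costs; FOLFOX runs 12 x 2-week cycles, CAPOX 8 x 3-week
#: cycles over 6 months, and the 3-month arms halve the number of cycles.
REGIMENS: Mapping[tuple[str, int], Regimen] = {
    ("CAPOX", 6): Regimen("CAPOX", 6, n_cycles=8, cycle_length_weeks=3, full_regimen_cost=11_843.0),
    ("CAPOX", 3): Regimen("CAPOX", 3, n_cycles=4, cycle_length_weeks=3, full_regimen_cost=5_982.0),
    ("FOLFOX", 6): Regimen("FOLFOX", 6, n_cycles=12, cycle_length_weeks=2, full_regimen_cost=19_563.0),
    ("FOLFOX", 3): Regimen("FOLFOX", 3, n_cycles=6, cycle_length_weeks=2, full_regimen_cost=10_284.0),
}


@dataclass(frozen=True)
class TreatmentEffect:
    """Hazard ratios composing the recurrence treatment effect of an arm.

    ``hr_6m_vs_none`` is the effect of 6 months of oxaliplatin-based
    chemotherapy versus no adjuvant treatment; ``hr_3v6`` the effect of
    shortening treatment from 6 to 3 months.  Confidence intervals feed
    the threshold and probabilistic sensitivity analyses (the interval
    for 0.73 is not published in the main text and is configurable).
    """

    hr_6m_vs_none: float = 0.73
    hr_3v6: float = 1.0
    hr_3v6_ci: tuple[float, float] = (0.88, 1.17)
    hr_6m_ci: tuple[float, float] = (0.65, 0.82)

    def __post_init__(self) -> None:
        for point, (lo, hi) in (
            (self.hr_6m_vs_none, self.hr_6m_ci),
            (self.hr_3v6, self.hr_3v6_ci),
        ):
            if point <= 0.0 or lo <= 0.0:
                raise ValueError("hazard ratios must be positive")
            if not lo <= point <= hi:
                raise ValueError("CI bounds must bracket the point estimate")


TREATMENT_EFFECTS: Mapping[str, TreatmentEffect] = {
    "CAPOX": TreatmentEffect(hr_3v6=1.0, hr_3v6_ci=(0.88, 1.17)),
    "FOLFOX": TreatmentEffect(hr_3v6=1.4, hr_3v6_ci=(1.19, 1.70)),
}


def effective_hr(effect: TreatmentEffect, duration: int) -> float:
    """Composed HR for recurrence versus no treatment for the given duration."""
    _check_duration(duration)
    if duration == 6:
        return effect.hr_6m_vs_none
    return effect.hr_6m_vs_none * effect.hr_3v6


@dataclass(frozen=True)
class AdverseEvent:
    name: str
    proportion_6m: float
    proportion_3m: float
    unit_cost: float

    def proportion(self, duration: int) -> float:
        _check_duration(duration)
        return self.proportion_6m if duration == 6 else self.proportion_3m


@dataclass(frozen=True)
class AdverseEventProfile:
    """Whole-regimen grade 3/4 toxicity proportions and follow-up costs per case."""

    events: tuple[AdverseEvent, ...]

    def __post_init__(self) -> None:
        for ev in self.events:
            for p in (ev.proportion_6m, ev.proportion_3m):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"adverse-event proportion out of [0,1] for {ev.name}")


DEFAULT_AE_PROFILE = AdverseEventProfile(
    events=(
        AdverseEvent("grade3_4_neutropenia", 0.249, 0.193, 95.0),
        AdverseEvent("febrile_neutropenia", 0.027, 0.014, 3309.0),
        AdverseEvent("grade3_4_diarrhea", 0.064, 0.051, 50.0),
    )
)


def expected_ae_cost(profile: AdverseEventProfile, duration: int) -> float:
    """Expected adverse-event cost per treated patient, applied once per regimen."""
    _check_duration(duration)
    return float(sum(ev.proportion(duration) * ev.unit_cost for ev in profile.events))


def chemo_window(duration: int) -> tuple[int, ...]:
    """Calendar months (since diagnosis) during which chemotherapy is delivered.

    Surgery and recovery occupy months 1-3, so chemotherapy runs over
    months 4..(3 + duration).  Per-cycle costs (travel, absenteeism) and
    drug administration are spread over this window.
    """
    _check_duration(duration)
    return tuple(range(4, 4 + duration))


# ---------------------------------------------------------------------------
# utility schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UtilityPeriod:
    """Arm-specific mean utility over a month range since diagnosis (95% CI)."""

    start_month: int
    end_month: int | None  # inclusive; None = open-ended
    utility_6m: float
    ci_6m: tuple[float, float]
    utility_3m: float
    ci_3m: tuple[float, float]

    def contains(self, month: int) -> bool:
        return month >= self.start_month and (self.end_month is None or month <= self.end_month)

    def value(self, duration: int, bound: str = "point") -> float:
        _check_duration(duration)
        u, ci = (self.utility_6m, self.ci_6m) if duration == 6 else (self.utility_3m, self.ci_3m)
        if bound == "point":
            return u
        if bound == "lower":
            return ci[0]
        if bound == "upper":
            return ci[1]
        raise ValueError(f"bound must be 'point', 'lower' or 'upper', got {bound!r}")


@dataclass(frozen=True)
class UtilitySchedule:
    """Health-state utilities by time since diagnosis and since recurrence.

    The period table covers the alive recurrence-free state; on
    recurrence the utility is 0.45 for months 1-60 since recurrence and
    the survivor utility (the >5-years-after-chemotherapy value, 0.90)
    thereafter.  The recurrence utility has no CI and is held fixed in
    sensitivity analyses.
    """

    periods: tuple[UtilityPeriod, ...]
    recurrence_utility: float = 0.45

    def __post_init__(self) -> None:
        # periods must partition months 1..inf without gaps or overlap
        expected = 1
        for i, p in enumerate(self.periods):
            if p.start_month != expected:
                raise ValueError("utility periods must partition months 1..inf")
            if p.end_month is None:
                if i != len(self.periods) - 1:
                    raise ValueError("only the last utility period may be open-ended")
            else:
                expected = p.end_month + 1
        if self.periods[-1].end_month is not None:
            raise ValueError("the last utility period must be open-ended")

    def period_for(self, month: int) -> UtilityPeriod:
        if month < 1:
            raise ValueError("month index starts at 1")
        for p in self.periods:
            if p.contains(month):
                return p
        raise AssertionError("unreachable: periods partition months 1..inf")

    def survivor_utility(self, duration: int, bound: str = "point") -> float:
        """Utility for cancer survivors >60 months after recurrence."""
        return self.periods[-1].value(duration, bound)

    def recurrence_free_vector(self, horizon: int, duration: int, bound: str = "point") -> np.ndarray:
        """Per-month utilities for the recurrence-free state, months 1..horizon."""
        return np.array([self.period_for(m).value(duration, bound) for m in range(1, horizon + 1)])


def utility_at(
    schedule: UtilitySchedule,
    month: int,
    state: HealthState,
    months_since_recurrence: int | None,
    duration: int,
    bound: str = "point",
) -> float:
    """Utility weight for one month in one health state.

    ``months_since_recurrence`` must be given iff the state is
    RECURRENCE; death states have utility 0.
    """
    if month < 1:
        raise ValueError("month index starts at 1")
    if state is HealthState.RECURRENCE:
        if months_since_recurrence is None:
            raise ValueError("months_since_recurrence required for the RECURRENCE state")
        if months_since_recurrence < 1:
            raise ValueError("months_since_recurrence starts at 1")
        if months_since_recurrence <= 60:
            return schedule.recurrence_utility
        return schedule.survivor_utility(duration, bound)
    if state is HealthState.DIAGNOSIS:
        return schedule.period_for(month).value(duration, bound)
    return 0.0


DEFAULT_UTILITY_SCHEDULE = UtilitySchedule(
    periods=(
        UtilityPeriod(1, 1, 0.83, (0.82, 0.84), 0.83, (0.82, 0.84)),
        UtilityPeriod(2, 3, 0.81, (0.80, 0.82), 0.81, (0.80, 0.82)),
        UtilityPeriod(4, 6, 0.81, (0.79, 0.83), 0.86, (0.84, 0.87)),
        UtilityPeriod(7, 9, 0.83, (0.81, 0.85), 0.87, (0.86, 0.88)),
        UtilityPeriod(10, 18, 0.85, (0.83, 0.87), 0.88, (0.86, 0.89)),
        UtilityPeriod(19, 60, 0.85, (0.82, 0.87), 0.88, (0.87, 0.90)),
        UtilityPeriod(61, None, 0.90, (0.84, 0.93), 0.90, (0.86, 0.96)),
    )
)
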