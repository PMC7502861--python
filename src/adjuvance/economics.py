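"""Cost and QALY accrual over a cohort trace, from the societal perspective.

Cost categories follow the trial-country (Dutch) costing study: initial
surgery and biomarker testing at diagnosis, drug acquisition over the
chemotherapy window, expected adverse-event follow-up care, patient
travel and productivity loss (friction-cost absenteeism) per
administered cycle, guideline surveillance until five years, and a
one-time lump sum on entry into the recurrence state.  All amounts are
2018 EUR.  Costs are discounted at 4% per year and health effects at
1.5% per year (Dutch guideline rates), with the monthly factor
``(1 + r)^(-(m - 1)/12)`` so the first month is undiscounted.

Accrual convention: month ``m`` is weighted by the state distribution
after the m-th transition (see :mod:`adjuvance.cohort_engine`); an
optional half-cycle correction averages the distributions before and
after the transition instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .cohort_engine import CohortTrace, SURVIVOR_COMPARTMENT
from .population import Subgroup
from .strategies import (
    AdverseEventProfile,
    Regimen,
    UtilitySchedule,
    chemo_window,
    expected_ae_cost,
)

__all__ = [
    "CostInputs",
    "SurveillanceSchedule",
    "DiscountRates",
    "StrategyOutcomes",
    "CostAccrual",
    "QalyAccrual",
    "discount_factor",
    "discount_vector",
    "age_band",
    "accrue_costs",
    "accrue_qalys",
    "summarize_outcomes",
]

AGE_BANDS = ("lt55", "55to65", "ge65")


@dataclass(frozen=True)
class CostInputs:
    """Unit costs (2018 EUR) outside the drug regimens themselves."""

    surgery: float = 12_987.0
    biomarker_test: float = 372.0
    travel_per_cycle: float = 8.0
    absenteeism_per_cycle: Mapping[str, float] = field(
        default_factory=lambda: {"lt55": 5_296.0, "55to65": 4_911.0, "ge65": 0.0}
    )
    colonoscopy: float = 850.0
    colonoscopy_with_complication: float = 1_430.0
    complication_probability: float = 0.028
    ultrasound: float = 83.0
    cea_test: float = 8.0
    relapse_lump_sum: float = 41_868.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.complication_probability <= 1.0:
            raise ValueError("complication probability must lie in [0, 1]")
        numeric = (
            self.surgery, self.biomarker_test, self.travel_per_cycle, self.colonoscopy,
            self.colonoscopy_with_complication, self.ultrasound, self.cea_test,
            self.relapse_lump_sum, *self.absenteeism_per_cycle.values(),
        )
        if any(v < 0.0 for v in numeric):
            raise ValueError("costs must be non-negative")

    def expected_colonoscopy_cost(self) -> float:
        p = self.complication_probability
        return (1.0 - p) * self.colonoscopy + p * self.colonoscopy_with_complication

    def consult_cost(self) -> float:
        return self.ultrasound + self.cea_test


@dataclass(frozen=True)
class SurveillanceSchedule:
    """Follow-up consultations (half-yearly to year 3, yearly to year 5) and colonoscopies."""

    consult_months: tuple[int, ...] = (6, 12, 18, 24, 30, 36, 48, 60)
    colonoscopy_months: tuple[int, ...] = (12, 48)

    def __post_init__(self) -> None:
        if any(m > 60 for m in self.consult_months + self.colonoscopy_months):
            raise ValueError("surveillance stops at 60 months")
        if not set(self.colonoscopy_months) <= set(range(1, max(self.consult_months) + 1)):
            raise ValueError("colonoscopy months must fall within the consult horizon")


@dataclass(frozen=True)
class DiscountRates:
    costs: float = 0.04
    effects: float = 0.015

    def __post_init__(self) -> None:
        if self.costs < 0.0 or self.effects < 0.0:
            raise ValueError("discount rates must be non-negative")


def discount_factor(month: int, annual_rate: float) -> float:
    """Discount factor for month ``m`` (1-based); the first month is undiscounted."""
    if month < 1:
        raise ValueError("month index starts at 1")
    return float((1.0 + annual_rate) ** (-(month - 1) / 12.0))


def discount_vector(horizon: int, annual_rate: float) -> np.ndarray:
    months = np.arange(1, horizon + 1, dtype=float)
    return (1.0 + annual_rate) ** (-(months - 1.0) / 12.0)


def age_band(subgroup: Subgroup) -> str:
    """Working-age band for absenteeism costing, from the age-bin midpoint."""
    mid = subgroup.age_midpoint
    if mid < 55.0:
        return "lt55"
    if mid < 65.0:
        return "55to65"
    return "ge65"


def quit_cost_multiplier(quit_proportion: float, fraction_incurred: float = 0.5) -> float:
    """Expected fraction of the full regimen cost actually incurred.

    Patients quitting before the end of the regimen (7%) incur
    ``fraction_incurred`` of the drug cost (default: half a regimen).
    """
    return 1.0 - quit_proportion * (1.0 - fraction_incurred)


def recurrence_free_cost_vectors(
    horizon: int,
    costs: CostInputs,
    regimen: Regimen,
    ae_profile: AdverseEventProfile,
    schedule: SurveillanceSchedule,
    band: str,
    quit_fraction_incurred: float = 0.5,
) -> dict[str, np.ndarray]:
    """Per-month cost streams applied to the alive recurrence-free occupancy.

    Returns one (horizon,) array per category (index 0 is month 1):
    drug, adverse_events, travel, absenteeism, surveillance.
    """
    window = chemo_window(regimen.duration)
    last_event = max(max(window), max(schedule.consult_months))
    if last_event > horizon:
        raise ValueError(f"scheduled month {last_event} lies beyond horizon {horizon}")
    vec = {k: np.zeros(horizon) for k in ("drug", "adverse_events", "travel", "absenteeism", "surveillance")}
    cycles_per_month = regimen.n_cycles / len(window)
    drug_per_month = (
        regimen.full_regimen_cost
        * quit_cost_multiplier(regimen.quit_proportion, quit_fraction_incurred)
        / len(window)
    )
    for m in window:
        vec["drug"][m - 1] = drug_per_month
        vec["travel"][m - 1] = costs.travel_per_cycle * cycles_per_month
        vec["absenteeism"][m - 1] = costs.absenteeism_per_cycle[band] * cycles_per_month
    vec["adverse_events"][window[0] - 1] = expected_ae_cost(ae_profile, regimen.duration)
    for m in schedule.consult_months:
        vec["surveillance"][m - 1] += costs.consult_cost()
    for m in schedule.colonoscopy_months:
        vec["surveillance"][m - 1] += costs.expected_colonoscopy_cost()
    return vec


@dataclass(frozen=True)
class CostAccrual:
    undiscounted: float
    discounted: float
    breakdown: Mapping[str, tuple[float, float]]  # category -> (undiscounted, discounted)


@dataclass(frozen=True)
class QalyAccrual:
    ly: float
    ly_discounted: float
    qaly: float
    qaly_discounted: float


def _month_weights(trace: CohortTrace, half_cycle: bool):
    """Occupancy weights for months 1..H: recurrence-free, tunnel clock, alive."""
    if half_cycle:
        occ = 0.5 * (trace.occupancy[:-1] + trace.occupancy[1:])
        clock = 0.5 * (trace.recurrence_clock[:-1] + trace.recurrence_clock[1:])
    else:
        occ = trace.occupancy[1:]
        clock = trace.recurrence_clock[1:]
    recfree = occ[:, 0]
    alive = occ[:, 0] + occ[:, 3]
    return recfree, clock, alive


def accrue_costs(
    trace: CohortTrace,
    costs: CostInputs,
    regimen: Regimen,
    ae_profile: AdverseEventProfile,
    schedule: SurveillanceSchedule,
    age_mix: str | Mapping[str, float],
    rates: DiscountRates,
    quit_fraction_incurred: float = 0.5,
    half_cycle: bool = False,
) -> CostAccrual:
    """Lifetime costs per patient, undiscounted and discounted.

    ``age_mix`` is either a single age band (per-subgroup accrual) or a
    mapping band -> population share (aggregated traces); it only affects
    the absenteeism stream.
    """
    horizon = trace.horizon
    if isinstance(age_mix, str):
        age_mix = {age_mix: 1.0}
    recfree, _, _ = _month_weights(trace, half_cycle)
    disc = discount_vector(horizon, rates.costs)
    per_band = {
        band: recurrence_free_cost_vectors(
            horizon, costs, regimen, ae_profile, schedule, band, quit_fraction_incurred
        )
        for band in age_mix
    }
    categories = next(iter(per_band.values())).keys()
    breakdown: dict[str, tuple[float, float]] = {}
    for cat in categories:
        stream = sum(share * per_band[band][cat] for band, share in age_mix.items()) * recfree
        breakdown[cat] = (float(stream.sum()), float(stream @ disc))
    oneoff = costs.surgery + costs.biomarker_test
    breakdown["surgery_and_staging"] = (oneoff, oneoff * discount_factor(1, rates.costs))
    relapse_stream = costs.relapse_lump_sum * trace.event_flows["recurrence"][1:]
    breakdown["relapse"] = (float(relapse_stream.sum()), float(relapse_stream @ disc))
    undisc = sum(v[0] for v in breakdown.values())
    disc_total = sum(v[1] for v in breakdown.values())
    return CostAccrual(undiscounted=float(undisc), discounted=float(disc_total), breakdown=breakdown)


def accrue_qalys(
    trace: CohortTrace,
    schedule: UtilitySchedule,
    duration: int,
    rates: DiscountRates,
    bound: str = "point",
    half_cycle: bool = False,
) -> QalyAccrual:
    """Life-years and QALYs per patient, undiscounted and discounted."""
    horizon = trace.horizon
    recfree, clock, alive = _month_weights(trace, half_cycle)
    u_free = schedule.recurrence_free_vector(horizon, duration, bound)
    u_surv = schedule.survivor_utility(duration, bound)
    q_month = (
        recfree * u_free
        + clock[:, :SURVIVOR_COMPARTMENT].sum(axis=1) * schedule.recurrence_utility
        + clock[:, SURVIVOR_COMPARTMENT] * u_surv
    )
    disc = discount_vector(horizon, rates.effects)
    return QalyAccrual(
        ly=float(alive.sum() / 12.0),
        ly_discounted=float((alive @ disc) / 12.0),
        qaly=float(q_month.sum() / 12.0),
        qaly_discounted=float((q_month @ disc) / 12.0),
    )


@dataclass(frozen=True)
class StrategyOutcomes:
    """Per-strategy epidemiological and economic endpoints.

    Event counts are lifetime totals per 1000 treated patients;
    life-years, QALYs and costs are per patient.
    """

    recurrences_per_1000: float
    cc_deaths_per_1000: float
    ly: float
    ly_discounted: float
    qaly: float
    qaly_discounted: float
    cost: float
    cost_discounted: float
    cost_breakdown: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        for count in (self.recurrences_per_1000, self.cc_deaths_per_1000):
            if not 0.0 <= count <= 1000.0 + 1e-6:
                raise ValueError("per-1000 counts must lie in [0, 1000]")


def summarize_outcomes(trace: CohortTrace, cost: CostAccrual, qaly: QalyAccrual) -> StrategyOutcomes:
    """Bundle lifetime event counts with the accrued economic endpoints."""
    return StrategyOutcomes(
        recurrences_per_1000=1000.0 * trace.cumulative_flow("recurrence"),
        cc_deaths_per_1000=1000.0 * trace.cumulative_flow("cc_death"),
        ly=qaly.ly,
        ly_discounted=qaly.ly_discounted,
        qaly=qaly.qaly,
        qaly_discounted=qaly.qaly_discounted,
        cost=cost.undiscounted,
        cost_discounted=cost.discounted,
        cost_breakdown=cost.breakdown,
    )
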