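"""Monthly-cycle five-state Markov cohort engine with recurrence tunnel states.

The disease model tracks a cohort of stage II colon cancer patients from
diagnosis to death through five health states: alive recurrence-free
(DIAGNOSIS), death within 90 days of surgery (NINETY_DAY_MORTALITY),
death by other causes, RECURRENCE, and death of colon cancer.  The three
death states are absorbing.  Time runs in 1-month cycles over a lifelong
horizon.

Transitions are driven by parametric proportional-hazards survival
models (recurrence clocked from diagnosis, colon cancer death clocked
from recurrence), an age-indexed other-cause mortality table, and a
per-subgroup 90-day mortality probability spread over the first three
cycles.  Because the colon-cancer death hazard and the recurrence
utility depend on time since recurrence, the RECURRENCE state is
expanded into monthly tunnel compartments (months 1..60 since
recurrence, then a single 60+ compartment).

Within a cycle, competing hazards are summed; the total exit probability
is ``1 - exp(-sum H)`` and is allocated to destinations proportionally to
their cumulative hazards over the cycle, which is exact for hazards
constant within the cycle.  Cycle accounting convention: ``occupancy[m]``
is the state distribution after the m-th transition, and month ``m`` of
any downstream accrual is weighted by ``occupancy[m]`` (deaths at the end
of a cycle do not accrue the month in which they occur; no half-cycle
correction by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .population import Subgroup, SubgroupWeights

__all__ = [
    "HealthState",
    "SurvivalModel",
    "TransitionInputs",
    "CohortTrace",
    "hazard_to_probability",
    "probability_to_hazard",
    "apply_hazard_ratio",
    "build_transition_row",
    "run_cohort",
    "run_cohorts",
    "aggregate_traces",
    "default_horizon",
    "N_TUNNEL",
    "SURVIVOR_COMPARTMENT",
]


class HealthState(IntEnum):
    DIAGNOSIS = 0
    NINETY_DAY_MORTALITY = 1
    DEATH_OTHER_CAUSES = 2
    RECURRENCE = 3
    DEATH_COLON_CANCER = 4


DEATH_STATES = (
    HealthState.NINETY_DAY_MORTALITY,
    HealthState.DEATH_OTHER_CAUSES,
    HealthState.DEATH_COLON_CANCER,
)

#: tunnel compartments within RECURRENCE: months 1..60 since recurrence plus one 60+ bin
N_TUNNEL = 61
SURVIVOR_COMPARTMENT = N_TUNNEL - 1  # index of the 60+ ("cancer survivor") bin

#: reference (centre) age bin for the per-bin age trend in the survival models
AGE_CENTER_INDEX = 4

ROW_SUM_TOL = 1e-12

SURVIVAL_FAMILIES = ("exponential", "weibull", "gompertz", "loglogistic", "lognormal")


# ---------------------------------------------------------------------------
# survival models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalModel:
    """Parametric proportional-hazards time-to-event model.

    ``params`` holds the family-specific baseline parameters with time in
    months: exponential ``rate``; weibull ``shape``/``scale``; gompertz
    ``rate``/``shape``; loglogistic ``shape``/``scale``; lognormal
    ``mu``/``sigma``.  ``covariate_log_hrs`` maps covariate levels
    (``"field=level"``) to log hazard ratios acting multiplicatively on
    the baseline hazard; the special key ``"age_per_bin"`` is a log-HR
    per 5-year age bin away from the centre bin.  ``param_ses`` and
    ``covariate_ses`` carry standard errors for probabilistic
    sensitivity analysis (log scale for positive baseline parameters,
    natural scale otherwise).
    """

    family: str
    params: Mapping[str, float]
    covariate_log_hrs: Mapping[str, float] = field(default_factory=dict)
    param_ses: Mapping[str, float] = field(default_factory=dict)
    covariate_ses: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in SURVIVAL_FAMILIES:
            raise ValueError(f"unknown survival family {self.family!r}")

    def cum_hazard(self, t) -> np.ndarray:
        """Baseline cumulative hazard at time ``t`` months (vectorised)."""
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.family == "exponential":
            return p["rate"] * t
        if self.family == "weibull":
            return (t / p["scale"]) ** p["shape"]
        if self.family == "gompertz":
            a, b = p["rate"], p["shape"]
            if abs(b) < 1e-12:
                return a * t
            return (a / b) * np.expm1(b * t)
        if self.family == "loglogistic":
            return np.log1p((t / p["scale"]) ** p["shape"])
        # lognormal
        with np.errstate(divide="ignore"):
            z = (np.log(np.maximum(t, 1e-300)) - p["mu"]) / p["sigma"]
        ch = -stats.norm.logsf(z)
        return np.where(t <= 0.0, 0.0, ch)

    def delta_cum_hazard(self, horizon: int) -> np.ndarray:
        """Per-cycle baseline cumulative hazard increments for months 1..horizon."""
        grid = self.cum_hazard(np.arange(horizon + 1, dtype=float))
        return np.diff(grid)

    def linear_predictor(self, subgroup: Subgroup) -> float:
        lp = 0.0
        for key, beta in self.covariate_log_hrs.items():
            if key == "age_per_bin":
                lp += beta * (subgroup.age_index - AGE_CENTER_INDEX)
                continue
            fld, _, level = key.partition("=")
            if getattr(subgroup, fld) == level:
                lp += beta
        return lp

    def hazard_multiplier(self, subgroup: Subgroup) -> float:
        return float(np.exp(self.linear_predictor(subgroup)))


@dataclass(frozen=True)
class TransitionInputs:
    """Everything the engine needs to build transition probabilities.

    ``other_cause_monthly_hazard`` maps integer attained age (years) to a
    monthly all-other-cause death hazard; lookups beyond the table are
    clamped to its last entry.  ``ninety_day_mortality`` maps each
    subgroup to the probability of death within 90 days of surgery,
    applied as three equal monthly hazards in cycles 1-3.
    """

    recurrence_model: SurvivalModel
    cc_death_model: SurvivalModel
    other_cause_monthly_hazard: Mapping[int, float]
    ninety_day_mortality: Mapping[Subgroup, float]

    def other_cause_hazard_at(self, age_years: float) -> float:
        ages = self._age_keys()
        key = int(np.floor(age_years))
        key = min(max(key, ages[0]), ages[-1])
        return float(self.other_cause_monthly_hazard[key])

    def _age_keys(self) -> Sequence[int]:
        return sorted(self.other_cause_monthly_hazard)


# ---------------------------------------------------------------------------
# elementary conversions
# ---------------------------------------------------------------------------


def hazard_to_probability(cumulative_hazard: float | np.ndarray) -> float | np.ndarray:
    """Probability of the event over one cycle given its cumulative hazard, 1 - exp(-H)."""
    h = np.asarray(cumulative_hazard, dtype=float)
    if np.any(h < 0.0):
        raise ValueError("cumulative hazard must be non-negative")
    out = -np.expm1(-h)
    return float(out) if out.ndim == 0 else out


def probability_to_hazard(p: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`hazard_to_probability`."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0.0) | (p >= 1.0)):
        raise ValueError("probability must lie in [0, 1)")
    out = -np.log1p(-p)
    return float(out) if out.ndim == 0 else out


def apply_hazard_ratio(p: float, hr: float) -> float:
    """Apply a hazard ratio to a per-cycle probability on the hazard scale.

    Returns ``1 - (1 - p)**hr``, i.e. the probability whose underlying
    constant hazard is ``hr`` times the hazard implied by ``p``.
    """
    if hr <= 0.0:
        raise ValueError("hazard ratio must be positive")
    if not 0.0 <= p < 1.0:
        raise ValueError("probability must lie in [0, 1)")
    return float(-np.expm1(hr * np.log1p(-p)))


def _competing_exit(hazards: Sequence[np.ndarray]):
    """Total exit probability and per-destination shares under competing hazards.

    Hazards are constant within the cycle, so each destination's share of
    the total exit probability equals its share of the summed cumulative
    hazard.
    """
    total = sum(hazards)
    p_exit = -np.expm1(-total)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = [np.where(total > 0.0, h / np.where(total > 0.0, total, 1.0), 0.0) for h in hazards]
    return p_exit, shares


# ---------------------------------------------------------------------------
# per-subgroup hazard arrays
# ---------------------------------------------------------------------------


class HazardArrays:
    """Precomputed per-cycle cumulative-hazard increments for a batch of subgroups.

    Rows index subgroups; ``rec(m)``/``oc(m)`` return the increments for
    cycle ``m`` (1-based), ``cc`` is the (rows x 61) tunnel-compartment
    increment matrix for the colon-cancer death hazard, and ``h90`` the
    monthly 90-day-mortality hazard applied in cycles 1-3.
    """

    def __init__(self, rec_dch: np.ndarray, oc_dch: np.ndarray, cc_dch: np.ndarray, h90: np.ndarray):
        self.rec_dch = rec_dch
        self.oc_dch = oc_dch
        self.cc = cc_dch
        self.h90 = h90
        self.n_rows = rec_dch.shape[0]
        for name, arr in (("recurrence", rec_dch), ("other-cause", oc_dch), ("cc-death", cc_dch), ("90-day", h90)):
            if not np.all(np.isfinite(arr)):
                idx = np.argwhere(~np.isfinite(arr))[0]
                raise ValueError(f"non-finite {name} hazard at index {tuple(idx)}")

    def rec(self, m: int) -> np.ndarray:
        return self.rec_dch[:, m - 1]

    def oc(self, m: int) -> np.ndarray:
        return self.oc_dch[:, m - 1]

    @classmethod
    def from_inputs(
        cls,
        subgroups: Sequence[Subgroup],
        inputs: TransitionInputs,
        horizon: int,
        survivor_cc_hazard: bool = True,
    ) -> "HazardArrays":
        base_rec = inputs.recurrence_model.delta_cum_hazard(horizon)
        base_cc = inputs.cc_death_model.delta_cum_hazard(N_TUNNEL)
        if not survivor_cc_hazard:
            base_cc = base_cc.copy()
            base_cc[SURVIVOR_COMPARTMENT] = 0.0
        rec_mult = np.array([inputs.recurrence_model.hazard_multiplier(s) for s in subgroups])
        cc_mult = np.array([inputs.cc_death_model.hazard_multiplier(s) for s in subgroups])
        rec_dch = rec_mult[:, None] * base_rec[None, :]
        cc_dch = cc_mult[:, None] * base_cc[None, :]
        months = np.arange(horizon)
        oc_dch = np.empty((len(subgroups), horizon))
        for i, s in enumerate(subgroups):
            ages = s.age_midpoint + months / 12.0
            oc_dch[i] = [inputs.other_cause_hazard_at(a) for a in ages]
        q90 = np.array([float(inputs.ninety_day_mortality[s]) for s in subgroups])
        if np.any((q90 < 0.0) | (q90 >= 1.0)):
            raise ValueError("90-day mortality probabilities must lie in [0, 1)")
        h90 = -np.log1p(-q90) / 3.0
        return cls(rec_dch, oc_dch, cc_dch, h90)


# ---------------------------------------------------------------------------
# trace container
# ---------------------------------------------------------------------------

FLOW_NAMES = ("recurrence", "cc_death", "other_death", "ninety_day_death")
FLOW_DESTINATION = {
    "recurrence": HealthState.RECURRENCE,
    "cc_death": HealthState.DEATH_COLON_CANCER,
    "other_death": HealthState.DEATH_OTHER_CAUSES,
    "ninety_day_death": HealthState.NINETY_DAY_MORTALITY,
}


@dataclass
class CohortTrace:
    """Cycle-by-state occupancy of one (or one weighted) cohort.

    ``occupancy[m]`` is the probability distribution over the five states
    after the m-th monthly transition (row 0 is the initial distribution:
    everyone in DIAGNOSIS).  ``recurrence_clock[m, k]`` splits the
    RECURRENCE occupancy by months since recurrence (k+1 for k < 60, the
    60+ survivor bin at k = 60).  ``event_flows[name][m]`` is the
    probability mass making the named transition during cycle m.
    """

    occupancy: np.ndarray
    recurrence_clock: np.ndarray
    event_flows: dict[str, np.ndarray]

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def alive(self) -> np.ndarray:
        return self.occupancy[:, HealthState.DIAGNOSIS] + self.occupancy[:, HealthState.RECURRENCE]

    @property
    def recurrence_free_alive(self) -> np.ndarray:
        return self.occupancy[:, HealthState.DIAGNOSIS]

    def cumulative_flow(self, name: str) -> float:
        return float(self.event_flows[name].sum())

    def validate(self, tol: float = ROW_SUM_TOL) -> None:
        row_sums = self.occupancy.sum(axis=1)
        if np.max(np.abs(row_sums - 1.0)) > tol:
            raise ValueError("occupancy rows do not sum to 1")
        clock_mass = self.recurrence_clock.sum(axis=1)
        if np.max(np.abs(clock_mass - self.occupancy[:, HealthState.RECURRENCE])) > tol:
            raise ValueError("recurrence clock mass does not match RECURRENCE occupancy")
        for name, flow in self.event_flows.items():
            if np.any(flow < -tol):
                raise ValueError(f"negative event flow in {name}")
            if flow.sum() > 1.0 + 1e-9:
                raise ValueError(f"cumulative {name} flow exceeds 1")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (cycle, state, occupancy, new_events) for CSV export."""
        records = []
        flows_by_state = {FLOW_DESTINATION[n].name: f for n, f in self.event_flows.items()}
        for m in range(self.horizon + 1):
            for state in HealthState:
                records.append(
                    {
                        "cycle": m,
                        "state": state.name,
                        "occupancy": self.occupancy[m, state],
                        "new_events": flows_by_state.get(state.name, np.zeros(self.horizon + 1))[m],
                    }
                )
        return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# single transition row (reference implementation of one matrix row)
# ---------------------------------------------------------------------------


def build_transition_row(
    state: HealthState,
    cycle: int,
    subgroup: Subgroup,
    inputs: TransitionInputs,
    effective_hr: float,
    months_since_recurrence: int = 1,
    survivor_cc_hazard: bool = True,
) -> np.ndarray:
    """One row of the transition matrix for the given state and cycle.

    The treatment-effect hazard ratio ``effective_hr`` scales only the
    DIAGNOSIS -> RECURRENCE hazard.  The 90-day mortality hazard acts
    only in cycles 1-3.  For the RECURRENCE state the colon-cancer death
    hazard depends on ``months_since_recurrence`` (tunnel compartment).
    """
    if cycle < 1:
        raise ValueError("cycle index starts at 1")
    if effective_hr <= 0.0:
        raise ValueError("effective hazard ratio must be positive")
    if not isinstance(state, HealthState):
        raise ValueError(f"unknown health state {state!r}")
    row = np.zeros(len(HealthState))
    if state in DEATH_STATES:
        row[state] = 1.0
        return row
    attained_age = subgroup.age_midpoint + (cycle - 1) / 12.0
    h_oc = inputs.other_cause_hazard_at(attained_age)
    if state is HealthState.DIAGNOSIS:
        base = inputs.recurrence_model
        h_rec = float(base.delta_cum_hazard(cycle)[-1]) * base.hazard_multiplier(subgroup) * effective_hr
        q90 = float(inputs.ninety_day_mortality[subgroup])
        h90 = -np.log1p(-q90) / 3.0 if cycle <= 3 else 0.0
        p_exit, (s_rec, s_oc, s_90) = _competing_exit(
            [np.asarray(h_rec), np.asarray(h_oc), np.asarray(h90)]
        )
        row[HealthState.RECURRENCE] = p_exit * s_rec
        row[HealthState.DEATH_OTHER_CAUSES] = p_exit * s_oc
        row[HealthState.NINETY_DAY_MORTALITY] = p_exit * s_90
        row[HealthState.DIAGNOSIS] = 1.0 - p_exit
        return row
    # RECURRENCE
    k = min(int(months_since_recurrence), N_TUNNEL) - 1
    if k < 0:
        raise ValueError("months_since_recurrence must be >= 1")
    base_cc = inputs.cc_death_model.delta_cum_hazard(N_TUNNEL)
    h_cc = float(base_cc[k]) * inputs.cc_death_model.hazard_multiplier(subgroup)
    if k == SURVIVOR_COMPARTMENT and not survivor_cc_hazard:
        h_cc = 0.0
    p_exit, (s_cc, s_oc) = _competing_exit([np.asarray(h_cc), np.asarray(h_oc)])
    row[HealthState.DEATH_COLON_CANCER] = p_exit * s_cc
    row[HealthState.DEATH_OTHER_CAUSES] = p_exit * s_oc
    row[HealthState.RECURRENCE] = 1.0 - p_exit
    return row


# ---------------------------------------------------------------------------
# cohort propagation
# ---------------------------------------------------------------------------


class TraceCollector:
    """Records full occupancy, tunnel clocks and event flows for each row."""

    def begin(self, n_rows: int, horizon: int) -> None:
        self.occupancy = np.zeros((horizon + 1, n_rows, len(HealthState)))
        self.clock = np.zeros((horizon + 1, n_rows, N_TUNNEL))
        self.flows = {name: np.zeros((horizon + 1, n_rows)) for name in FLOW_NAMES}
        self.occupancy[0, :, HealthState.DIAGNOSIS] = 1.0

    def cycle(self, m, d, r, dead90, dead_oc, dead_cc, flows) -> None:
        self.occupancy[m, :, HealthState.DIAGNOSIS] = d
        self.occupancy[m, :, HealthState.RECURRENCE] = r.sum(axis=1)
        self.occupancy[m, :, HealthState.NINETY_DAY_MORTALITY] = dead90
        self.occupancy[m, :, HealthState.DEATH_OTHER_CAUSES] = dead_oc
        self.occupancy[m, :, HealthState.DEATH_COLON_CANCER] = dead_cc
        self.clock[m] = r
        for name in FLOW_NAMES:
            self.flows[name][m] = flows[name]

    def traces(self) -> list[CohortTrace]:
        n_rows = self.occupancy.shape[1]
        return [
            CohortTrace(
                occupancy=self.occupancy[:, i, :].copy(),
                recurrence_clock=self.clock[:, i, :].copy(),
                event_flows={name: self.flows[name][:, i].copy() for name in FLOW_NAMES},
            )
            for i in range(n_rows)
        ]


def propagate(haz: HazardArrays, effective_hr, horizon: int, collectors: Sequence) -> None:
    """Run the monthly state-transition recursion, feeding per-cycle results to collectors.

    ``effective_hr`` may be a scalar or a per-row array.  Collectors
    receive, after each cycle m, the post-transition DIAGNOSIS occupancy,
    the tunnel-compartment matrix, the absorbing-state masses and the
    per-cycle event flows.
    """
    if horizon < 1:
        raise ValueError("horizon must be at least one cycle")
    ehr = np.asarray(effective_hr, dtype=float)
    if np.any(ehr <= 0.0):
        raise ValueError("effective hazard ratio must be positive")
    n = haz.n_rows
    d = np.ones(n)
    r = np.zeros((n, N_TUNNEL))
    dead90 = np.zeros(n)
    dead_oc = np.zeros(n)
    dead_cc = np.zeros(n)
    for c in collectors:
        c.begin(n, horizon)
    zeros = np.zeros(n)
    for m in range(1, horizon + 1):
        h_rec = haz.rec(m) * ehr
        h_oc = haz.oc(m)
        h_90 = haz.h90 if m <= 3 else zeros
        p_exit, (s_rec, s_oc, s_90) = _competing_exit([h_rec, h_oc, h_90])
        exit_d = d * p_exit
        new_rec = exit_d * s_rec
        new_ocd = exit_d * s_oc
        new_90d = exit_d * s_90
        d = d - exit_d
        # recurrence tunnel: colon-cancer death competes with other-cause death
        h_cc = haz.cc
        total_r = h_cc + h_oc[:, None]
        p_exit_r = -np.expm1(-total_r)
        with np.errstate(invalid="ignore", divide="ignore"):
            share_cc = np.where(total_r > 0.0, h_cc / np.where(total_r > 0.0, total_r, 1.0), 0.0)
        exit_r = r * p_exit_r
        new_ccd = (exit_r * share_cc).sum(axis=1)
        new_ocd = new_ocd + (exit_r * (1.0 - share_cc)).sum(axis=1)
        stay = r - exit_r
        r = np.zeros_like(r)
        r[:, 1:] = stay[:, :-1]
        r[:, SURVIVOR_COMPARTMENT] += stay[:, SURVIVOR_COMPARTMENT]
        r[:, 0] = new_rec
        dead90 = dead90 + new_90d
        dead_oc = dead_oc + new_ocd
        dead_cc = dead_cc + new_ccd
        flows = {
            "recurrence": new_rec,
            "cc_death": new_ccd,
            "other_death": new_ocd,
            "ninety_day_death": new_90d,
        }
        for c in collectors:
            c.cycle(m, d, r, dead90, dead_oc, dead_cc, flows)


def default_horizon(subgroups: Sequence[Subgroup], max_age: float = 100.0) -> int:
    """Months until the youngest age-bin midpoint reaches ``max_age`` ("lifelong")."""
    youngest = min(s.age_midpoint for s in subgroups)
    return int(np.ceil((max_age - youngest) * 12.0))


def run_cohorts(
    subgroups: Sequence[Subgroup],
    inputs: TransitionInputs,
    effective_hr: float,
    horizon: int | None = None,
    survivor_cc_hazard: bool = True,
) -> list[CohortTrace]:
    """Run the cohort recursion for several subgroups at once (vectorised)."""
    if horizon is None:
        horizon = default_horizon(subgroups)
    haz = HazardArrays.from_inputs(subgroups, inputs, horizon, survivor_cc_hazard)
    collector = TraceCollector()
    propagate(haz, effective_hr, horizon, [collector])
    return collector.traces()


def run_cohort(
    subgroup: Subgroup,
    inputs: TransitionInputs,
    effective_hr: float,
    horizon: int | None = None,
    survivor_cc_hazard: bool = True,
) -> CohortTrace:
    """Lifelong cohort trace for a single subgroup (cohort starts in DIAGNOSIS)."""
    return run_cohorts([subgroup], inputs, effective_hr, horizon, survivor_cc_hazard)[0]


def aggregate_traces(
    traces: Mapping[Subgroup, CohortTrace], weights: SubgroupWeights
) -> CohortTrace:
    """Weight-average cohort traces over subgroups.

    Weights must sum to 1 over the provided traces; all traces must share
    one horizon.
    """
    subgroups = list(traces)
    w = np.array([weights[s] for s in subgroups])
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights do not sum to 1 over the provided traces")
    horizons = {traces[s].horizon for s in subgroups}
    if len(horizons) != 1:
        raise ValueError(f"mismatched trace horizons: {sorted(horizons)}")
    occupancy = sum(wi * traces[s].occupancy for wi, s in zip(w, subgroups))
    clock = sum(wi * traces[s].recurrence_clock for wi, s in zip(w, subgroups))
    flows = {
        name: sum(wi * traces[s].event_flows[name] for wi, s in zip(w, subgroups))
        for name in FLOW_NAMES
    }
    return CohortTrace(occupancy=occupancy, recurrence_clock=clock, event_flows=flows)
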