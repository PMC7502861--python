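"""Decision-analytic endpoints and sensitivity analyses.

Incremental comparisons are always 3-month strategy versus the 6-month
reference on discounted endpoints: incremental net monetary benefit
iNMB = dQALY x lambda - dCost at a willingness to pay of EUR 50,000 per
QALY, the ICER dCost/dQALY with its cost-effectiveness-plane quadrant
(SE = cheaper and more effective, i.e. dominant; the ICER is then
reported as a negative ratio with a dominance flag), a hazard-ratio
threshold analysis over the 3-vs-6-month HR confidence interval, a
one-way analysis moving all scheduled utilities to their CI bounds, and
a probabilistic sensitivity analysis (PSA).

The PSA draws every uncertain parameter jointly: utilities ~ Beta
matched to mean and 95% CI (the recurrence utility, printed without a
CI, is fixed), unit costs ~ Gamma with CV 0.2 where no CI is printed,
hazard ratios ~ Lognormal matched to point and CI, adverse-event
proportions ~ Beta, survival-model coefficients ~ Normal on their fitted
scale, a common Lognormal multiplier on other-cause mortality and a
common Normal logit shift on 90-day mortality.  All draws are
independent, and one joint draw is applied to BOTH strategy arms of an
iteration (common random parameters), so the incremental pair of every
iteration is internally consistent.  Acceptability curves report, per
willingness-to-pay value, the fraction of iterations in which each
strategy attains the maximal net monetary benefit (ties go to the
lower-cost strategy).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_engine import SURVIVOR_COMPARTMENT, HazardArrays, propagate, default_horizon
from .economics import (
    AGE_BANDS,
    CostInputs,
    StrategyOutcomes,
    age_band,
    discount_vector,
    recurrence_free_cost_vectors,
)
from .population import select_high_risk
from .strategies import AdverseEvent, AdverseEventProfile, REGIMENS, TreatmentEffect

__all__ = [
    "CEAComparison",
    "ThresholdCurve",
    "PSASampleSet",
    "CEACCurve",
    "PSAResult",
    "compare",
    "threshold_analysis",
    "oneway_utilities",
    "run_psa",
    "ceac_from_samples",
    "DEFAULT_WTP",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_WTP = 50_000.0
DEFAULT_LAMBDA_GRID = np.arange(0.0, 100_001.0, 1_000.0)

_Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# incremental comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CEAComparison:
    """Incremental comparison of an alternative against a reference strategy."""

    delta_cost: float
    delta_qaly: float
    icer: float | None
    quadrant: str
    inmb: float
    wtp: float

    @property
    def dominant(self) -> bool:
        """True when the alternative is cheaper and more effective (SE quadrant)."""
        return self.quadrant == "SE"


def compare(
    reference: StrategyOutcomes, alternative: StrategyOutcomes, wtp: float = DEFAULT_WTP
) -> CEAComparison:
    """Incremental cost-effectiveness of ``alternative`` versus ``reference``.

    Differences are taken on discounted endpoints.  The ICER is flagged
    undefined (None) when the QALY difference is zero; a dominant
    (SE-quadrant) comparison reports the negative ratio as printed in
    cost-effectiveness tables.
    """
    dq = alternative.qaly_discounted - reference.qaly_discounted
    dc = alternative.cost_discounted - reference.cost_discounted
    quadrant = ("S" if dc <= 0.0 else "N") + ("E" if dq >= 0.0 else "W")
    icer = None if dq == 0.0 else dc / dq
    return CEAComparison(
        delta_cost=dc,
        delta_qaly=dq,
        icer=icer,
        quadrant=quadrant,
        inmb=dq * wtp - dc,
        wtp=wtp,
    )


# ---------------------------------------------------------------------------
# threshold analysis on the 3-vs-6-month hazard ratio
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdCurve:
    """Incremental endpoints of the 3-month arm over a grid of 3-vs-6-month HRs."""

    hr_grid: np.ndarray
    delta_qaly: np.ndarray
    delta_cost: np.ndarray
    inmb: np.ndarray
    icer: np.ndarray  # NaN where dQALY = 0
    first_hr_qaly_loss: float | None
    first_hr_not_cost_effective: float | None
    wtp: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hr_3v6": self.hr_grid,
                "delta_qaly": self.delta_qaly,
                "delta_cost": self.delta_cost,
                "inmb": self.inmb,
                "icer": self.icer,
            }
        )


def hr_grid_from_ci(effect: TreatmentEffect, step: float = 0.01) -> np.ndarray:
    """Grid from the point estimate towards the adverse CI bound of hr_3v6.

    The direction mirrors the one-way variation of the published
    analysis: upward from the point for an HR at or below 1 (towards the
    upper CI limit), downward to the lower limit otherwise.
    """
    lo, hi = effect.hr_3v6_ci
    if effect.hr_3v6 <= 1.0 + 1e-12:
        start, stop = effect.hr_3v6, hi
    else:
        start, stop = lo, effect.hr_3v6
    n = int(round((stop - start) / step))
    return np.round(np.linspace(start, stop, n + 1), 12)


def threshold_analysis(
    reference: StrategyOutcomes,
    hr_grid: Sequence[float],
    runner_3m: Callable[[float], StrategyOutcomes],
    wtp: float = DEFAULT_WTP,
) -> ThresholdCurve:
    """Re-run the 3-month strategy at each grid HR against a fixed 6-month reference.

    The reference keeps its base-case treatment effect (HR 0.73 versus no
    treatment).  Records the first grid HR at which the 3-month strategy
    loses QALYs and the first at which it stops being cost effective
    (iNMB < 0 at the stated willingness to pay).
    """
    grid = np.asarray(list(hr_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if np.any(np.diff(grid) <= 0.0):
        raise ValueError("threshold grid must be strictly increasing")
    dq = np.empty(grid.size)
    dc = np.empty(grid.size)
    for i, hr in enumerate(grid):
        comparison = compare(reference, runner_3m(float(hr)), wtp)
        dq[i] = comparison.delta_qaly
        dc[i] = comparison.delta_cost
    inmb = dq * wtp - dc
    with np.errstate(divide="ignore", invalid="ignore"):
        icer = np.where(dq != 0.0, dc / np.where(dq != 0.0, dq, 1.0), np.nan)
    qaly_loss = np.flatnonzero(dq < 0.0)
    not_ce = np.flatnonzero(inmb < 0.0)
    return ThresholdCurve(
        hr_grid=grid,
        delta_qaly=dq,
        delta_cost=dc,
        inmb=inmb,
        icer=icer,
        first_hr_qaly_loss=float(grid[qaly_loss[0]]) if qaly_loss.size else None,
        first_hr_not_cost_effective=float(grid[not_ce[0]]) if not_ce.size else None,
        wtp=wtp,
    )


# ---------------------------------------------------------------------------
# one-way utility analysis
# ---------------------------------------------------------------------------


def oneway_utilities(
    bound: str,
    runner: Callable[[int, str], StrategyOutcomes],
    wtp: float = DEFAULT_WTP,
) -> dict:
    """Re-run both strategy arms with all scheduled utilities at a CI bound.

    ``runner(duration, bound)`` must return the arm's outcomes with the
    utility schedule evaluated at the bound; transitions (and hence
    recurrences and deaths) are unaffected, the recurrence utility has no
    CI and stays at its point value.
    """
    if bound not in ("lower", "upper"):
        raise ValueError("bound must be 'lower' or 'upper'")
    ref = runner(6, bound)
    alt = runner(3, bound)
    return {"6m": ref, "3m": alt, "comparison": compare(ref, alt, wtp)}


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSASampleSet:
    """Joint Monte-Carlo parameter draws and the per-iteration strategy endpoints."""

    n: int
    seed: int
    draws: Mapping[str, np.ndarray]
    cost_discounted: np.ndarray  # (n, 2): columns 6m, 3m
    qaly_discounted: np.ndarray
    recurrences_per_1000: np.ndarray
    strategy_labels: tuple[str, str] = ("6m", "3m")


@dataclass(frozen=True)
class CEACCurve:
    """Probability of attaining the highest NMB per willingness-to-pay value."""

    lambda_grid: np.ndarray
    probabilities: np.ndarray  # (len(grid), n_strategies)
    strategy_labels: tuple[str, ...]

    def probability(self, label: str, wtp: float) -> float:
        j = self.strategy_labels.index(label)
        i = int(np.argmin(np.abs(self.lambda_grid - wtp)))
        return float(self.probabilities[i, j])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.probabilities, columns=list(self.strategy_labels))
        frame.insert(0, "wtp", self.lambda_grid)
        return frame


@dataclass(frozen=True)
class PSAResult:
    samples: PSASampleSet
    ce_plane: pd.DataFrame  # iteration, delta_cost, delta_qaly (3m - 6m)
    ceac: CEACCurve


def ceac_from_samples(
    samples: PSASampleSet, lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID
) -> CEACCurve:
    """Acceptability curve over a willingness-to-pay grid; ties go to the cheaper arm."""
    lam = np.asarray(lambda_grid, dtype=float)
    nmb = lam[:, None, None] * samples.qaly_discounted[None] - samples.cost_discounted[None]
    best = np.argmax(nmb, axis=2)
    tie = nmb[..., 0] == nmb[..., 1]
    cheaper = np.argmin(samples.cost_discounted, axis=1)
    best = np.where(tie, cheaper[None, :], best)
    probs = np.stack([(best == j).mean(axis=1) for j in range(2)], axis=1)
    return CEACCurve(
        lambda_grid=lam, probabilities=probs, strategy_labels=samples.strategy_labels
    )


# -- distribution helpers ----------------------------------------------------


class DistributionSpecError(ValueError):
    """Raised when a PSA distribution cannot be built; names the parameter."""


def _lognormal_ci(rng, n, point, ci, scale, name):
    if point <= 0.0 or ci[0] <= 0.0 or ci[1] < ci[0]:
        raise DistributionSpecError(f"invalid lognormal spec for parameter {name!r}")
    sigma = (np.log(ci[1]) - np.log(ci[0])) / (2.0 * _Z95) * scale
    if sigma == 0.0:
        return np.full(n, float(point))
    return np.exp(rng.normal(np.log(point), sigma, n))


def _normal(rng, n, mean, sd, scale, name):
    sd = sd * scale
    if sd < 0.0:
        raise DistributionSpecError(f"negative spread for parameter {name!r}")
    if sd == 0.0:
        return np.full(n, float(mean))
    return rng.normal(mean, sd, n)


def _lognormal_sd(rng, n, point, log_sd, scale, name):
    if point <= 0.0 or log_sd < 0.0:
        raise DistributionSpecError(f"invalid lognormal spec for parameter {name!r}")
    log_sd = log_sd * scale
    if log_sd == 0.0:
        return np.full(n, float(point))
    return np.exp(rng.normal(np.log(point), log_sd, n))


def _beta_mean_ci(rng, n, mean, ci, scale, name):
    sd = (ci[1] - ci[0]) / (2.0 * _Z95) * scale
    if sd == 0.0:
        return np.full(n, float(mean))
    if not 0.0 < mean < 1.0:
        raise DistributionSpecError(f"Beta mean outside (0, 1) for parameter {name!r}")
    var = min(sd**2, 0.99 * mean * (1.0 - mean))
    k = mean * (1.0 - mean) / var - 1.0
    return rng.beta(mean * k, (1.0 - mean) * k, n)


def _beta_ess(rng, n, p, ess, scale, name):
    if not 0.0 <= p <= 1.0:
        raise DistributionSpecError(f"Beta proportion outside [0, 1] for parameter {name!r}")
    if scale == 0.0 or p in (0.0, 1.0):
        return np.full(n, float(p))
    ess = ess / scale**2
    return rng.beta(p * ess, (1.0 - p) * ess, n)


def _gamma_cv(rng, n, mean, cv, scale, name):
    if mean < 0.0:
        raise DistributionSpecError(f"negative Gamma mean for parameter {name!r}")
    cv = cv * scale
    if cv == 0.0 or mean == 0.0:
        return np.full(n, float(mean))
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean / shape, n)


#: effective sample size behind the adverse-event proportion Beta draws
AE_PROPORTION_ESS = 500.0
#: coefficient of variation for unit costs printed without a CI
COST_CV = 0.2


def _draw_survival_params(rng, n, model, scale):
    """Draw baseline parameters and covariate log-HRs of one survival model.

    Positive baseline parameters (rates, shapes, scales, sigma) get
    Lognormal draws with the stored SE on the log scale; location
    parameters (mu) and covariate log-HRs get Normal draws.
    """
    params = {}
    for name, value in model.params.items():
        se = model.param_ses.get(name, 0.0)
        if name == "mu":
            params[name] = _normal(rng, n, value, se, scale, f"{model.family}.{name}")
        else:
            params[name] = _lognormal_sd(rng, n, value, se, scale, f"{model.family}.{name}")
    betas = {}
    for name, value in model.covariate_log_hrs.items():
        se = model.covariate_ses.get(name, 0.0)
        betas[name] = _normal(rng, n, value, se, scale, f"{model.family}.{name}")
    return params, betas


def _survival_multipliers(subgroups, betas, n):
    """exp(X beta) per (iteration, subgroup) for drawn covariate effects."""
    from .cohort_engine import AGE_CENTER_INDEX

    lp = np.zeros((n, len(subgroups)))
    for j, s in enumerate(subgroups):
        for key, draw in betas.items():
            if key == "age_per_bin":
                lp[:, j] += draw * (s.age_index - AGE_CENTER_INDEX)
            else:
                fld, _, level = key.partition("=")
                if getattr(s, fld) == level:
                    lp[:, j] += draw
    return np.exp(lp)


def _baseline_delta_ch(family, params, horizon):
    """Per-cycle baseline cumulative-hazard increments for n drawn parameter rows."""
    t = np.arange(horizon + 1, dtype=float)[None, :]
    if family == "exponential":
        ch = params["rate"][:, None] * t
    elif family == "weibull":
        ch = (t / params["scale"][:, None]) ** params["shape"][:, None]
    elif family == "gompertz":
        a, b = params["rate"][:, None], params["shape"][:, None]
        ch = np.where(np.abs(b) < 1e-12, a * t, (a / np.where(b == 0, 1.0, b)) * np.expm1(b * t))
    elif family == "loglogistic":
        ch = np.log1p((t / params["scale"][:, None]) ** params["shape"][:, None])
    elif family == "lognormal":
        from scipy import stats

        with np.errstate(divide="ignore"):
            z = (np.log(np.maximum(t, 1e-300)) - params["mu"][:, None]) / params["sigma"][:, None]
        ch = np.where(t <= 0.0, 0.0, -stats.norm.logsf(z))
    else:  # pragma: no cover - families are validated upstream
        raise ValueError(f"unknown survival family {family!r}")
    return np.diff(ch, axis=1)


class _PSAHazards:
    """Batched hazard source: rows are (iteration x high-risk subgroup) pairs."""

    def __init__(self, rec_base, rec_mult, oc_table, oc_factor, cc_full, h90, iter_idx, sub_idx):
        self._rec_base = rec_base  # (n, H)
        self._rec_mult = rec_mult  # (B,)
        self._oc_table = oc_table  # (S, H)
        self._oc_factor = oc_factor  # (n,)
        self.cc = cc_full  # (B, 61)
        self.h90 = h90  # (B,)
        self._it = iter_idx
        self._sub = sub_idx
        self.n_rows = rec_mult.shape[0]

    def rec(self, m):
        return self._rec_base[self._it, m - 1] * self._rec_mult

    def oc(self, m):
        return self._oc_table[self._sub, m - 1] * self._oc_factor[self._it]


class _PSAEconCollector:
    """Accrues discounted cost and QALY per batch row during propagation."""

    def __init__(self, iter_idx, sub_idx, band_idx, cost_mat, u_free, u_surv, u_rec, relapse, disc_c, disc_e):
        self._it = iter_idx
        self._sub = sub_idx
        self._band = band_idx
        self._cost_mat = cost_mat  # (3, n, H)
        self._u_free = u_free  # (n, H)
        self._u_surv = u_surv  # (n,)
        self._u_rec = u_rec
        self._relapse = relapse  # (n,)
        self._disc_c = disc_c
        self._disc_e = disc_e

    def begin(self, n_rows, horizon):
        self.cost = np.zeros(n_rows)
        self.qaly = np.zeros(n_rows)
        self.recurrences = np.zeros(n_rows)
        self.cc_deaths = np.zeros(n_rows)

    def cycle(self, m, d, r, dead90, dead_oc, dead_cc, flows):
        it = self._it
        c = self._cost_mat[self._band, it, m - 1] * d + self._relapse[it] * flows["recurrence"]
        self.cost += c * self._disc_c[m - 1]
        q = (
            d * self._u_free[it, m - 1]
            + r[:, :SURVIVOR_COMPARTMENT].sum(axis=1) * self._u_rec
            + r[:, SURVIVOR_COMPARTMENT] * self._u_surv[it]
        )
        self.qaly += q * self._disc_e[m - 1] / 12.0
        self.recurrences += flows["recurrence"]
        self.cc_deaths += flows["cc_death"]


def run_psa(
    params,
    drug: str,
    n: int = 1000,
    seed: int = 0,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    horizon: int | None = None,
    uncertainty_scale: float = 1.0,
    quit_fraction_incurred: float = 0.5,
    survivor_cc_hazard: bool = True,
    wtp: float = DEFAULT_WTP,
    chunk_size: int = 100,
) -> PSAResult:
    """Probabilistic sensitivity analysis for one drug (3-month vs 6-month arm).

    ``params`` is a :class:`~adjuvance.synthetic_params.ParameterSet`.
    Each of the ``n`` iterations applies one joint parameter draw to both
    strategy arms, runs the full cohort model for the high-risk cohort
    and accrues discounted costs and QALYs.  ``uncertainty_scale``
    linearly scales every distribution's spread (0 collapses the PSA to
    the base case).  Draws are reproducible bit for bit given the seed.
    """
    if n < 1:
        raise ValueError("PSA needs at least one iteration")
    rng = np.random.default_rng(seed)
    high_risk = select_high_risk(params.weights)
    subgroups = high_risk.subgroups
    S = len(subgroups)
    weights = np.array([high_risk[s] for s in subgroups])
    if horizon is None:
        horizon = default_horizon(subgroups)
    ti = params.transition_inputs
    effect = params.treatment_effects[drug]
    sc = uncertainty_scale

    # --- joint parameter draws (order fixed for reproducibility) ----------
    draws: dict[str, np.ndarray] = {}
    draws["hr_6m_vs_none"] = _lognormal_ci(rng, n, effect.hr_6m_vs_none, effect.hr_6m_ci, sc, "hr_6m_vs_none")
    draws["hr_3v6"] = _lognormal_ci(rng, n, effect.hr_3v6, effect.hr_3v6_ci, sc, "hr_3v6")
    rec_params, rec_betas = _draw_survival_params(rng, n, ti.recurrence_model, sc)
    cc_params, cc_betas = _draw_survival_params(rng, n, ti.cc_death_model, sc)
    draws["other_cause_multiplier"] = _lognormal_sd(rng, n, 1.0, params.other_cause_log_se, sc, "other_cause_multiplier")
    draws["ninety_day_logit_shift"] = _normal(rng, n, 0.0, params.ninety_day_logit_se, sc, "ninety_day_logit_shift")

    ci = params.cost_inputs
    cost_draws = {
        name: _gamma_cv(rng, n, getattr(ci, name), COST_CV, sc, name)
        for name in (
            "surgery", "biomarker_test", "travel_per_cycle", "colonoscopy",
            "colonoscopy_with_complication", "ultrasound", "cea_test", "relapse_lump_sum",
        )
    }
    absent_draws = {
        band: _gamma_cv(rng, n, ci.absenteeism_per_cycle[band], COST_CV, sc, f"absenteeism_{band}")
        for band in AGE_BANDS
    }
    regimen_cost_draws = {
        dur: _gamma_cv(rng, n, REGIMENS[(drug, dur)].full_regimen_cost, COST_CV, sc, f"regimen_cost_{dur}m")
        for dur in (6, 3)
    }
    ae_draws = {
        ev.name: {
            "p6": _beta_ess(rng, n, ev.proportion_6m, AE_PROPORTION_ESS, sc, f"{ev.name}_6m"),
            "p3": _beta_ess(rng, n, ev.proportion_3m, AE_PROPORTION_ESS, sc, f"{ev.name}_3m"),
            "cost": _gamma_cv(rng, n, ev.unit_cost, COST_CV, sc, f"{ev.name}_cost"),
        }
        for ev in params.ae_profile.events
    }
    schedule = params.utility_schedule
    util_draws = {
        6: np.column_stack(
            [_beta_mean_ci(rng, n, p.utility_6m, p.ci_6m, sc, f"utility_6m_{p.start_month}") for p in schedule.periods]
        ),
        3: np.column_stack(
            [_beta_mean_ci(rng, n, p.utility_3m, p.ci_3m, sc, f"utility_3m_{p.start_month}") for p in schedule.periods]
        ),
    }
    for dur in (6, 3):
        draws[f"utilities_{dur}m"] = util_draws[dur]

    # --- per-iteration hazard structures ----------------------------------
    rec_base = _baseline_delta_ch(ti.recurrence_model.family, rec_params, horizon)
    cc_base = _baseline_delta_ch(ti.cc_death_model.family, cc_params, SURVIVOR_COMPARTMENT + 1)
    if not survivor_cc_hazard:
        cc_base[:, SURVIVOR_COMPARTMENT] = 0.0
    rec_mult_is = _survival_multipliers(subgroups, rec_betas, n)  # (n, S)
    cc_mult_is = _survival_multipliers(subgroups, cc_betas, n)

    point_haz = HazardArrays.from_inputs(subgroups, ti, horizon, survivor_cc_hazard)
    oc_table = point_haz.oc_dch  # (S, H), shared table scaled by the common multiplier
    q90_base = np.array([ti.ninety_day_mortality[s] for s in subgroups])
    shift = draws["ninety_day_logit_shift"]
    if np.all(shift == 0.0):
        q90_is = np.broadcast_to(q90_base, (n, S))
    else:
        logit = np.log(q90_base / (1.0 - q90_base))[None, :] + shift[:, None]
        q90_is = 1.0 / (1.0 + np.exp(-logit))
    h90_is = -np.log1p(-q90_is) / 3.0

    # --- per-iteration economic structures --------------------------------
    period_idx = np.array(
        [next(i for i, p in enumerate(schedule.periods) if p.contains(m)) for m in range(1, horizon + 1)]
    )
    disc_c = discount_vector(horizon, params.discount_rates.costs)
    disc_e = discount_vector(horizon, params.discount_rates.effects)
    oneoff = cost_draws["surgery"] + cost_draws["biomarker_test"]
    cost_mats = {}
    for dur in (6, 3):
        mat = np.empty((len(AGE_BANDS), n, horizon))
        for i in range(n):
            ci_i = CostInputs(
                surgery=float(cost_draws["surgery"][i]),
                biomarker_test=float(cost_draws["biomarker_test"][i]),
                travel_per_cycle=float(cost_draws["travel_per_cycle"][i]),
                absenteeism_per_cycle={b: float(absent_draws[b][i]) for b in AGE_BANDS},
                colonoscopy=float(cost_draws["colonoscopy"][i]),
                colonoscopy_with_complication=float(cost_draws["colonoscopy_with_complication"][i]),
                complication_probability=ci.complication_probability,
                ultrasound=float(cost_draws["ultrasound"][i]),
                cea_test=float(cost_draws["cea_test"][i]),
                relapse_lump_sum=float(cost_draws["relapse_lump_sum"][i]),
            )
            ae_i = AdverseEventProfile(
                events=tuple(
                    AdverseEvent(
                        ev.name,
                        float(ae_draws[ev.name]["p6"][i]),
                        float(ae_draws[ev.name]["p3"][i]),
                        float(ae_draws[ev.name]["cost"][i]),
                    )
                    for ev in params.ae_profile.events
                )
            )
            regimen = dataclasses.replace(
                REGIMENS[(drug, dur)], full_regimen_cost=float(regimen_cost_draws[dur][i])
            )
            for bi, band in enumerate(AGE_BANDS):
                mat[bi, i] = sum(
                    recurrence_free_cost_vectors(
                        horizon, ci_i, regimen, ae_i, params.surveillance, band,
                        quit_fraction_incurred,
                    ).values()
                )
        cost_mats[dur] = mat

    # --- batched propagation, chunked over iterations to stay cache-friendly
    band_of_sub = np.array([AGE_BANDS.index(age_band(s)) for s in subgroups])
    u_free_all = {dur: util_draws[dur][:, period_idx] for dur in (6, 3)}
    ehr_all = {
        6: draws["hr_6m_vs_none"],
        3: draws["hr_6m_vs_none"] * draws["hr_3v6"],
    }
    cost_pp = np.empty((n, 2))
    qaly_pp = np.empty((n, 2))
    rec_per_1000 = np.empty((n, 2))
    for start in range(0, n, chunk_size):
        sl = slice(start, min(start + chunk_size, n))
        nc = sl.stop - sl.start
        iter_loc = np.repeat(np.arange(nc), S)
        sub_idx = np.tile(np.arange(S), nc)
        row_w = weights[sub_idx]
        haz = _PSAHazards(
            rec_base=rec_base[sl],
            rec_mult=rec_mult_is[sl][iter_loc, sub_idx],
            oc_table=oc_table,
            oc_factor=draws["other_cause_multiplier"][sl],
            cc_full=cc_base[sl][iter_loc] * cc_mult_is[sl][iter_loc, sub_idx][:, None],
            h90=h90_is[sl][iter_loc, sub_idx],
            iter_idx=iter_loc,
            sub_idx=sub_idx,
        )
        for col, dur in enumerate((6, 3)):
            collector = _PSAEconCollector(
                iter_idx=iter_loc,
                sub_idx=sub_idx,
                band_idx=band_of_sub[sub_idx],
                cost_mat=cost_mats[dur][:, sl],
                u_free=u_free_all[dur][sl],
                u_surv=util_draws[dur][sl, -1],
                u_rec=schedule.recurrence_utility,
                relapse=cost_draws["relapse_lump_sum"][sl],
                disc_c=disc_c,
                disc_e=disc_e,
            )
            propagate(haz, ehr_all[dur][sl][iter_loc], horizon, [collector])
            cost_pp[sl, col] = (
                np.bincount(iter_loc, weights=row_w * collector.cost, minlength=nc) + oneoff[sl]
            )
            qaly_pp[sl, col] = np.bincount(iter_loc, weights=row_w * collector.qaly, minlength=nc)
            rec_per_1000[sl, col] = 1000.0 * np.bincount(
                iter_loc, weights=row_w * collector.recurrences, minlength=nc
            )

    samples = PSASampleSet(
        n=n,
        seed=seed,
        draws=draws,
        cost_discounted=cost_pp,
        qaly_discounted=qaly_pp,
        recurrences_per_1000=rec_per_1000,
    )
    ce_plane = pd.DataFrame(
        {
            "iteration": np.arange(n),
            "delta_cost": cost_pp[:, 1] - cost_pp[:, 0],
            "delta_qaly": qaly_pp[:, 1] - qaly_pp[:, 0],
        }
    )
    ceac = ceac_from_samples(samples, lambda_grid)
    return PSAResult(samples=samples, ce_plane=ce_plane, ceac=ceac)
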