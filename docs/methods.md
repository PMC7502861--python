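# Methods

This note documents the model, its numerical conventions, the synthetic
parameter generator, and the design choices made where the published
description leaves the implementation open.

## Cohort model

A Markov cohort model propagates state-occupancy probabilities through five
health states (alive recurrence-free; 90-day mortality; death by other
causes; recurrence; death of colon cancer) in 1-month cycles. "Lifelong" is
operationalised as running until the youngest age-bin midpoint reaches 100
years (570 cycles for the full 50–95 grid); remaining alive mass at that
point is negligible under any realistic mortality input.

**Competing risks within a cycle.** Hazards are taken as constant within a
cycle. For per-cause cumulative hazards *H₁…H_k* over the cycle, the exit
probability is 1 − exp(−ΣH) and is allocated to destinations proportionally
to *H_k* — the exact solution for constant hazards, verified in the test
suite against numerical integration of the competing-risk integral.

**Recurrence tunnel.** The recurrence state carries 61 monthly compartments
(months 1–60 since recurrence, then a single 60+ bin). This makes two
time-since-recurrence dependencies exact: the parametric colon-cancer death
hazard, and the utility switch from 0.45 to the survivor value at month 60.
By default the 60+ compartment retains the colon-cancer death hazard
(evaluated on its last monthly interval); the published wording makes the
60-month boundary a statement about utility only, so survivors are not
biologically "cured" in the model. A switch (`survivor_cc_hazard=False`)
zeroes that hazard instead.

**90-day mortality.** Each subgroup's 90-day death probability *q* is
converted to three equal monthly hazards, −ln(1−q)/3, applied in cycles 1–3
in competition with the recurrence and other-cause hazards. Deaths from
each hazard are attributed to their own state, so the 90-day state absorbs
exactly *q* when the other hazards vanish.

**Cycle accounting.** Month *m* of every cost and QALY stream is weighted
by the state distribution *after* the *m*-th transition; a patient does not
accrue the month in which they die. Under this convention a constant
monthly death probability *p* yields a life expectancy of (1−p)/p months,
which the suite checks against the trace to 1e-10. No half-cycle correction
is applied by default (`half_cycle=True` averages the pre- and
post-transition distributions instead); with monthly cycles the correction
is second-order.

**Attained age.** Other-cause mortality is looked up by integer attained
age = age-bin midpoint + elapsed months, clamped to the table range.

## Strategies and economics

The four arms combine drug (CAPOX: 8×3-week cycles; FOLFOX: 12×2-week
cycles; halved in the 3-month arms) with the composed recurrence hazard
ratio 0.73 (6-month arms) or 0.73 × HR₃ᵥ₆ (3-month arms; 1.0 for CAPOX,
1.4 for FOLFOX). Chemotherapy occupies calendar months 4–6 (3-month arms)
or 4–9 (6-month arms), following the utility-period labels that place
surgery and recovery in months 1–3.

Cost accrual per patient (2018 EUR): surgery (€12,987) and biomarker
testing (€372) once at month 1; the printed full-regimen drug cost spread
uniformly over the chemotherapy window, weighted by the alive
recurrence-free occupancy and multiplied by 1 − 0.07 × 0.5 — the 7 % who
quit early are assumed to incur half a regimen (the incurred fraction is a
config knob, since the source lists only the quit percentage); travel (€8)
and age-band absenteeism (€5,296 / €4,911 / €0 per cycle) per administered
cycle, cycles mapped uniformly into the window; the expected adverse-event
cost (proportion × unit cost summed over grade 3/4 neutropenia, febrile
neutropenia, diarrhea) once at treatment start — adverse events are costs,
not health states, and carry no separate disutility because the
arm-specific SCOT utilities already reflect on-treatment quality of life;
surveillance (consultations with ultrasound + CEA at months 6–60,
colonoscopies with a 2.8 % complication rate at months 12 and 48) while
recurrence-free, never restarted for survivors; and a €41,868 lump sum on
each entry into recurrence. Discounting uses (1+r)^(−(m−1)/12) with
r = 4 %/year for costs and 1.5 %/year for effects; the first month is
undiscounted. Setting both rates to zero reproduces the undiscounted
streams identically.

QALYs multiply occupancy by the SCOT period utilities (arm-specific, with
95 % CIs), 0.45 in recurrence months 1–60, and the survivor utility —
taken to be the ">5 years after chemotherapy" value of the same arm, whose
CI it follows in the one-way analysis; the recurrence utility is published
without a CI and is held fixed everywhere.

## Decision analysis

Comparisons are 3-month versus 6-month arm on discounted endpoints:
iNMB = ΔQALY·λ − ΔCost at λ = €50,000/QALY, ICER = ΔCost/ΔQALY (undefined
at ΔQALY = 0; reported as a negative ratio with a dominance flag in the
southeast quadrant). The threshold analysis re-runs the 3-month arm on a
0.01-step HR grid from the point estimate towards the adverse CI bound
(1.0→1.17 for CAPOX, 1.19→1.40 for FOLFOX) against the fixed base-case
reference, reporting the first grid HR with a QALY loss and the first with
iNMB < 0. The one-way analysis moves all scheduled utilities to a CI bound
in both arms; transitions are untouched, so event counts are provably
unchanged.

**PSA distributions** (the source states only "most appropriate
distribution"; each choice is a package default, overridable via the
parameter set): utilities ~ Beta matched to mean and 95 % CI; unit costs ~
Gamma with CV 0.2 where no CI is printed; hazard ratios ~ Lognormal matched
to point and CI (the unpublished CI of the 0.73 HR defaults to a synthetic
0.65–0.82); adverse-event proportions ~ Beta with an effective sample size
of 500 (a TOSCA-scale arm); survival coefficients ~ Normal on the fitted
scale (log scale for positive baseline parameters) with the generator's
standard errors; other-cause mortality scaled by a common Lognormal
multiplier (σ = 0.05 on the log) and 90-day mortality shifted by a common
Normal logit offset (σ = 0.10), since no per-subgroup uncertainty is
published. All draws are independent; one joint draw drives both arms of an
iteration (common random parameters); ties in the acceptability curve go
to the cheaper arm. 1000 iterations are the default. Because the
3-vs-6-month HR is itself drawn, the CAPOX acceptability probability at
€50,000/QALY settles near 0.9 rather than at exactly 1 — roughly the
probability mass of the HR interval below the ≈1.07 QALY-loss threshold —
which is the internally consistent consequence of including treatment-
effect uncertainty in the joint draw.

An `uncertainty_scale` factor multiplies every spread; at 0 the PSA
collapses to the base case exactly, which the suite exploits as an
identity check.

## Synthetic parameter generator

The analysis consumes registry-fitted coefficients that are not public, so
the generator writes a complete, schema-valid parameter set directly (it
never fits models): a Weibull recurrence baseline (shape 0.8, scale 700
months) with covariate log-HRs (inadequate nodal harvest +0.26, T4 +0.79,
right-sided +0.18, MSI −0.60, MSS-with-mutation +0.22, +0.03 per 5-year age
bin); a lognormal recurrence-to-death model (μ = 3.05 ≈ 21-month median,
σ = 1.10) with small age and mutation effects; Gompertz other-cause
mortality (annual hazard 0.0035·e^{0.10·(age−50)}, tabulated monthly for
ages 50–110); logistic-in-age 90-day mortality (≈0.6 % at 70 for T3, ×e^0.4
for T4); and population weights as a product of jittered covariate
marginals peaked in the early seventies. Each block draws from its own
named substream of the seed, so perturbing one block leaves the others
bitwise unchanged. Every published cost, utility, adverse-event and
hazard-ratio input is embedded at its printed value.

The recurrence and mortality magnitudes were calibrated once so the
weighted 6-month high-risk cohort lands on the scale of the published
base case — 352 recurrences and 290 colon-cancer deaths per 1000 treated
patients, 9.4 undiscounted / 8.4 discounted life-years and 7.06 discounted
QALYs per patient, and an untreated 5-year recurrence risk of 0.24 — and
frozen. What the generator does **not** emulate: correlation between
survival coefficients (independent draws), non-proportional hazards,
treatment-effect waning, heterogeneity beyond the 216-cell grid, or the
actual Dutch covariate distribution. Passing tests therefore demonstrate
that the pipeline's mechanics (bookkeeping, accrual, decision statistics,
Monte-Carlo machinery) are correct and that its qualitative conclusions are
robust on realistic inputs — not that the numerical endpoints equal those
obtainable only with the registry coefficients.

## Microsimulation oracle

An independent check replays the model at the individual level: patients
are assigned subgroups by weight and walked through the same monthly
transition probabilities by inverse-CDF sampling, with identical cost and
utility accounting. Cohort-trace occupancies and mean discounted
cost/QALYs must agree within three binomial / Monte-Carlo standard errors
(200,000 individuals over 120 cycles in the acceptance suite; 40,000 in the
unit tests). The oracle shares the hazard *inputs* but none of the matrix
propagation code path.

## Numerical conventions and degenerate inputs

Probability bookkeeping is enforced to 1e-12 per cycle. Zero total hazard
leaves occupancy fixed (0/0 shares are defined as 0). Weight tables are
serialized with 17 significant digits and re-read with round-trip float
parsing, making CSV and YAML round trips lossless. PSA results are bitwise
reproducible for a given seed and invariant to the internal iteration
chunk size. Empty high-risk mass, non-finite hazards (named by transition),
invalid distribution specs (named by parameter), schedule months beyond the
horizon, and non-bracketing confidence intervals all raise immediately.

## Known limitations

Treatment effects are constant multipliers (no waning); dose reductions,
mid-course switching and metastasis-site detail are out of scope;
post-recurrence care is a single lump sum; absenteeism uses age-band
per-cycle values with friction-period capping assumed embedded in them; and
the cross-drug comparison (CAPOX vs FOLFOX) is provided only as an
explicitly labelled exploratory report, since the strategy question is
duration within drug.
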