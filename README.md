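# adjuvance

Cost-effectiveness analysis of **3 versus 6 months of oxaliplatin-based
adjuvant chemotherapy** (CAPOX and FOLFOX) in **high-risk stage II colon
cancer** (T4 tumours with microsatellite-stable biology), built as a tested,
reusable Python pipeline for health economists and decision modellers.

Shortening adjuvant chemotherapy halves oxaliplatin exposure — and with it
chronic neuropathy, toxicity costs and time lost to treatment — but pooled
trial evidence says the price differs by regimen: 3 months of CAPOX is as
effective as 6 (HR 1.0, 95% CI 0.88–1.17 for recurrence), while 3 months of
FOLFOX is clearly worse (HR 1.4, 95% CI 1.19–1.70). This package quantifies
that trade-off in quality-adjusted life-years (QALYs) and 2018 euros from the
societal perspective.

## Model

The core is a **Markov cohort state-transition model** with a 1-month cycle
and a lifelong horizon, five health states — alive recurrence-free,
90-day (surgical) mortality, death by other causes, recurrence, and death of
colon cancer — and 216 patient subgroups (lymph-node harvest × T stage ×
tumour site × nine 5-year age bins × biomarker status), weighted to the
national stage II case mix and filtered to the high-risk T4+MSS cells.

Transitions come from parametric proportional-hazards survival models.
For cycle *m* with per-cause cumulative hazards
*H<sub>k</sub>* the exit probability is 1 − exp(−Σ<sub>k</sub>H<sub>k</sub>),
allocated across causes in proportion to the *H<sub>k</sub>*. The treatment
effect multiplies the recurrence hazard: HR 0.73 versus no treatment for the
6-month arms, 0.73 × HR<sub>3v6</sub> for the 3-month arms. The recurrence
state is expanded into monthly tunnel compartments so that the colon-cancer
death hazard depends on time since recurrence and the utility switches from
0.45 (recurrence, months 1–60) to 0.90 (cancer survivor) exactly at 60
months.

Costs (surgery, biomarker testing, drugs, adverse events, travel,
friction-cost absenteeism, guideline surveillance, a relapse lump sum) and
SCOT-trial utilities are accrued per cycle and discounted at the Dutch
reference rates (4 % costs, 1.5 % effects). Strategies are compared by the
incremental net monetary benefit

> iNMB = ΔQALY × λ − ΔCost,  λ = €50,000/QALY,

the ICER ΔCost/ΔQALY with its cost-effectiveness-plane quadrant, a
hazard-ratio threshold analysis, a one-way utility analysis, and a
1000-iteration probabilistic sensitivity analysis with cost-effectiveness
acceptability curves.

Because the registry-fitted survival coefficients behind the original model
are not public, the package ships a **synthetic parameter generator** that
emulates their statistical structure (Weibull recurrence with covariate
log-HRs, lognormal post-recurrence survival, Gompertz other-cause mortality,
logistic 90-day mortality) while embedding every published cost, utility,
adverse-event and hazard-ratio input at its printed value, plus a
**microsimulation oracle** that replays individual trajectories against the
deterministic cohort trace. See `docs/methods.md` for assumptions and
limitations.

## Worked example

```bash
$ adjuvance run --seed 1 --out results
CAPOX: dQALY=+0.108 dCost=-9479 iNMB=+14903 (SE)
FOLFOX: dQALY=-0.544 dCost=-11632 iNMB=-15552 (SW)
wrote 3 files to results
```

With the seed-1 synthetic parameter set, shortening CAPOX to 3 months leaves
recurrences and colon-cancer deaths untouched (352 and 290 per 1000 treated
patients in both arms — the 3-vs-6 HR is 1.0), gains 0.108 discounted QALYs
per patient through better on-treatment quality of life, and saves €9,479 per
patient, i.e. the 3-month strategy *dominates* (southeast quadrant, iNMB
+€14,903). For FOLFOX the HR of 1.4 raises deaths from 290 to 364 per 1000
and costs 0.544 QALYs per patient; the €11,632 saving does not compensate at
€50,000/QALY (iNMB −€15,552, southwest quadrant) — 6 months remains the
better FOLFOX strategy. The same conclusions as the published analysis, on
synthetic transition inputs.

```bash
$ adjuvance threshold --drug CAPOX --seed 1 --out results
CAPOX: first HR with QALY loss 1.07, first HR not cost effective 1.16
```

The 3-month CAPOX advantage is fragile: a 3-vs-6-month HR of just 1.07
(within the 0.88–1.17 confidence interval) already erases the QALY gain.
The same library calls are available programmatically:

```python
from adjuvance import generate_parameter_set, run_psa
from adjuvance.workbench import ModelRunner

params = generate_parameter_set(seed=1)
runner = ModelRunner(params, "CAPOX")
print(runner.outcomes(3).qaly_discounted)   # 7.168...
psa = run_psa(params, "FOLFOX", n=1000, seed=1)
print(psa.ceac.probability("6m", 50_000))   # probability 6m has the highest NMB
```

Other entry points: `adjuvance generate` (write a parameter file),
`adjuvance oneway --bound lower|upper`, `adjuvance psa --drug ... [--plot]`.

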