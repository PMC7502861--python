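"""Pipeline orchestration: configuration, base-case runs, reports and the CLI.

Ties population selection, the cohort engine, strategy definitions and
the economic layer into strategy-level endpoint tables (recurrences and
colon-cancer deaths per 1000 treated patients, life-years, QALYs and
costs per patient, discounted and undiscounted), the incremental
comparison of the 3-month versus the 6-month arm per drug, and the three
sensitivity analyses.  Every emitted table can be regenerated from the
run manifest (seed, configuration digest, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cea import (
    DEFAULT_WTP,
    compare,
    hr_grid_from_ci,
    oneway_utilities,
    run_psa,
    threshold_analysis,
)
from .cohort_engine import CohortTrace, default_horizon, run_cohorts
from .economics import (
    StrategyOutcomes,
    accrue_costs,
    accrue_qalys,
    age_band,
    summarize_outcomes,
)
from .population import SubgroupWeights, select_high_risk
from .strategies import DRUGS, REGIMENS, effective_hr
from .synthetic_params import ParameterSet, generate_parameter_set, load_parameter_file

logger = logging.getLogger("adjuvance")

__all__ = ["RunConfig", "ModelRunner", "run_base_case", "render_report", "cli"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run."""

    drugs: tuple[str, ...] = ("CAPOX", "FOLFOX")
    wtp: float = DEFAULT_WTP
    seed: int = 0
    parameter_file: str | None = None  # falls back to the synthetic generator
    horizon: int | None = None  # default: until the youngest bin midpoint turns 100
    n_psa: int = 1000
    threshold_step: float = 0.01
    half_cycle: bool = False
    quit_fraction_incurred: float = 0.5
    survivor_cc_hazard: bool = True
    utility_bound: str = "point"
    output_dir: str = "results"

    def __post_init__(self) -> None:
        unknown = set(self.drugs) - set(DRUGS)
        if unknown:
            raise ValueError(f"unknown drugs in config: {sorted(unknown)}")
        if self.utility_bound not in ("point", "lower", "upper"):
            raise ValueError("utility_bound must be point, lower or upper")
        if self.parameter_file is not None and not Path(self.parameter_file).exists():
            raise FileNotFoundError(f"parameter file not found: {self.parameter_file}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "drugs" in data:
            data["drugs"] = tuple(data["drugs"])
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def load_parameters(self) -> ParameterSet:
        if self.parameter_file is not None:
            return load_parameter_file(self.parameter_file)
        return generate_parameter_set(self.seed)


class ModelRunner:
    """Evaluates strategy arms for one drug on the high-risk (T4+MSS) cohort.

    Caches cohort traces by effective hazard ratio: with the CAPOX
    3-vs-6-month HR of 1.0 both arms share one trace, which also makes
    their epidemiological outputs identical by construction.
    """

    def __init__(
        self,
        params: ParameterSet,
        drug: str,
        horizon: int | None = None,
        half_cycle: bool = False,
        quit_fraction_incurred: float = 0.5,
        survivor_cc_hazard: bool = True,
    ):
        if drug not in DRUGS:
            raise ValueError(f"unknown drug {drug!r}")
        self.params = params
        self.drug = drug
        self.high_risk: SubgroupWeights = select_high_risk(params.weights)
        self.subgroups = self.high_risk.subgroups
        self.horizon = horizon if horizon is not None else default_horizon(self.subgroups)
        self.half_cycle = half_cycle
        self.quit_fraction_incurred = quit_fraction_incurred
        self.survivor_cc_hazard = survivor_cc_hazard
        self._trace_cache: dict[float, list[CohortTrace]] = {}

    def traces(self, effective_hr_value: float) -> list[CohortTrace]:
        key = float(effective_hr_value)
        if key not in self._trace_cache:
            self._trace_cache[key] = run_cohorts(
                self.subgroups,
                self.params.transition_inputs,
                key,
                self.horizon,
                self.survivor_cc_hazard,
            )
        return self._trace_cache[key]

    def effective_hr(self, duration: int, hr_3v6_override: float | None = None) -> float:
        effect = self.params.treatment_effects[self.drug]
        if hr_3v6_override is not None:
            effect = dataclasses.replace(effect, hr_3v6=hr_3v6_override)
        return effective_hr(effect, duration)

    def outcomes(
        self,
        duration: int,
        hr_3v6_override: float | None = None,
        utility_bound: str = "point",
    ) -> StrategyOutcomes:
        """Weighted strategy endpoints over the high-risk cohort."""
        ehr = self.effective_hr(duration, hr_3v6_override)
        traces = self.traces(ehr)
        regimen = REGIMENS[(self.drug, duration)]
        per_subgroup = []
        for s, trace in zip(self.subgroups, traces):
            cost = accrue_costs(
                trace,
                self.params.cost_inputs,
                regimen,
                self.params.ae_profile,
                self.params.surveillance,
                age_band(s),
                self.params.discount_rates,
                self.quit_fraction_incurred,
                self.half_cycle,
            )
            qaly = accrue_qalys(
                trace,
                self.params.utility_schedule,
                duration,
                self.params.discount_rates,
                utility_bound,
                self.half_cycle,
            )
            per_subgroup.append(summarize_outcomes(trace, cost, qaly))
        w = np.array([self.high_risk[s] for s in self.subgroups])
        return combine_outcomes(per_subgroup, w)


def combine_outcomes(outcomes, weights) -> StrategyOutcomes:
    """Population-weighted average of per-subgroup strategy outcomes."""
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("subgroup weights must sum to 1")

    def avg(attr):
        return float(sum(wi * getattr(o, attr) for wi, o in zip(w, outcomes)))

    categories = outcomes[0].cost_breakdown.keys()
    breakdown = {
        cat: (
            float(sum(wi * o.cost_breakdown[cat][0] for wi, o in zip(w, outcomes))),
            float(sum(wi * o.cost_breakdown[cat][1] for wi, o in zip(w, outcomes))),
        )
        for cat in categories
    }
    return StrategyOutcomes(
        recurrences_per_1000=avg("recurrences_per_1000"),
        cc_deaths_per_1000=avg("cc_deaths_per_1000"),
        ly=avg("ly"),
        ly_discounted=avg("ly_discounted"),
        qaly=avg("qaly"),
        qaly_discounted=avg("qaly_discounted"),
        cost=avg("cost"),
        cost_discounted=avg("cost_discounted"),
        cost_breakdown=breakdown,
    )


def endpoint_row(drug: str, duration: int, o: StrategyOutcomes) -> dict:
    return {
        "drug": drug,
        "strategy": f"{duration}m",
        "recurrences_per_1000": o.recurrences_per_1000,
        "cc_deaths_per_1000": o.cc_deaths_per_1000,
        "ly": o.ly,
        "ly_discounted": o.ly_discounted,
        "qaly": o.qaly,
        "qaly_discounted": o.qaly_discounted,
        "cost": o.cost,
        "cost_discounted": o.cost_discounted,
    }


def run_base_case(config: RunConfig, params: ParameterSet | None = None) -> dict:
    """Four-arm base-case endpoint table plus per-drug incremental comparisons."""
    if params is None:
        params = config.load_parameters()
    rows, comparisons, breakdown_rows = [], {}, []
    outcomes: dict[tuple[str, int], StrategyOutcomes] = {}
    for drug in config.drugs:
        runner = ModelRunner(
            params,
            drug,
            config.horizon,
            config.half_cycle,
            config.quit_fraction_incurred,
            config.survivor_cc_hazard,
        )
        per_arm = {}
        for duration in (6, 3):
            o = runner.outcomes(duration, utility_bound=config.utility_bound)
            per_arm[duration] = o
            outcomes[(drug, duration)] = o
            rows.append(endpoint_row(drug, duration, o))
            for cat, (undisc, disc) in o.cost_breakdown.items():
                breakdown_rows.append(
                    {
                        "drug": drug,
                        "strategy": f"{duration}m",
                        "category": cat,
                        "undiscounted": undisc,
                        "discounted": disc,
                    }
                )
        comparisons[drug] = compare(per_arm[6], per_arm[3], config.wtp)
        logger.info(
            "%s: iNMB(3m vs 6m) = %.0f EUR at WTP %.0f", drug, comparisons[drug].inmb, config.wtp
        )
    endpoints = pd.DataFrame(rows)
    endpoints["inmb_vs_6m"] = [
        comparisons[r["drug"]].inmb if r["strategy"] == "3m" else np.nan for r in rows
    ]
    endpoints["icer_vs_6m"] = [
        (comparisons[r["drug"]].icer if r["strategy"] == "3m" else np.nan) for r in rows
    ]
    endpoints["quadrant"] = [
        comparisons[r["drug"]].quadrant if r["strategy"] == "3m" else "" for r in rows
    ]
    return {
        "endpoints": endpoints,
        "comparisons": comparisons,
        "cost_breakdown": pd.DataFrame(breakdown_rows),
        "outcomes": outcomes,
        "params": params,
    }


def cross_drug_report(outcomes: dict, wtp: float = DEFAULT_WTP) -> pd.DataFrame:
    """Exploratory cross-drug comparisons (reference labelled explicitly per row)."""
    rows = []
    for ref_key, alt_key in (
        (("FOLFOX", 3), ("CAPOX", 3)),
        (("FOLFOX", 6), ("CAPOX", 3)),
    ):
        if ref_key in outcomes and alt_key in outcomes:
            c = compare(outcomes[ref_key], outcomes[alt_key], wtp)
            rows.append(
                {
                    "reference": f"{ref_key[0]} {ref_key[1]}m",
                    "alternative": f"{alt_key[0]} {alt_key[1]}m",
                    "delta_qaly": c.delta_qaly,
                    "delta_cost": c.delta_cost,
                    "inmb": c.inmb,
                    "quadrant": c.quadrant,
                }
            )
    return pd.DataFrame(rows)


def render_report(results: dict, config: RunConfig, out_dir) -> dict[str, Path]:
    """Write endpoint/breakdown/PSA tables as CSV plus a reproducibility manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def write_frame(name: str, frame: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        written[name] = path

    if "endpoints" in results:
        write_frame("endpoints", results["endpoints"])
    if "cost_breakdown" in results:
        write_frame("cost_breakdown", results["cost_breakdown"])
    for drug in DRUGS:
        key = f"threshold_{drug}"
        if key in results:
            write_frame(key, results[key].to_frame())
        key = f"psa_{drug}"
        if key in results:
            write_frame(f"ce_plane_{drug}", results[key].ce_plane)
            write_frame(f"ceac_{drug}", results[key].ceac.to_frame())
    if "oneway" in results:
        write_frame("oneway", results["oneway"])
    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "package_version": __version__,
        "outputs": sorted(written),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    written["manifest"] = manifest_path
    return written


# ---------------------------------------------------------------------------
# command-line interface
# ---------------------------------------------------------------------------

import click  # noqa: E402


def _load_config(config_path, **overrides) -> RunConfig:
    if config_path is not None:
        cfg = RunConfig.from_yaml(config_path)
        if overrides:
            cfg = dataclasses.replace(cfg, **overrides)
        return cfg
    return RunConfig(**overrides)


@click.group()
@click.option("-v", "--verbose", count=True, help="Increase logging verbosity.")
def cli(verbose: int) -> None:
    """Cost-effectiveness model for 3 vs 6 months of adjuvant chemotherapy."""
    level = logging.WARNING - 10 * min(verbose, 2)
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")


@cli.command()
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", type=click.Path(dir_okay=False), required=True)
def generate(seed: int, out: str) -> None:
    """Write a complete synthetic parameter file (YAML)."""
    params = generate_parameter_set(seed)
    params.to_yaml(out)
    click.echo(f"wrote {out} ({params.provenance})")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--params", "parameter_file", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "output_dir", type=click.Path(file_okay=False), default="results")
def run(config_path, parameter_file, seed, output_dir) -> None:
    """Base-case endpoint and cost-decomposition tables for both drugs."""
    cfg = _load_config(
        config_path, parameter_file=parameter_file, seed=seed, output_dir=output_dir
    )
    results = run_base_case(cfg)
    written = render_report(results, cfg, cfg.output_dir)
    for comparison_drug, comparison in results["comparisons"].items():
        click.echo(
            f"{comparison_drug}: dQALY={comparison.delta_qaly:+.3f} "
            f"dCost={comparison.delta_cost:+.0f} iNMB={comparison.inmb:+.0f} "
            f"({comparison.quadrant})"
        )
    click.echo(f"wrote {len(written)} files to {cfg.output_dir}")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--drug", type=click.Choice(DRUGS), required=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "output_dir", type=click.Path(file_okay=False), default="results")
def threshold(config_path, drug, seed, output_dir) -> None:
    """Threshold analysis over the 3-vs-6-month hazard-ratio confidence interval."""
    cfg = _load_config(config_path, seed=seed, output_dir=output_dir, drugs=(drug,))
    params = cfg.load_parameters()
    runner = ModelRunner(
        params, drug, cfg.horizon, cfg.half_cycle, cfg.quit_fraction_incurred,
        cfg.survivor_cc_hazard,
    )
    curve = threshold_analysis(
        runner.outcomes(6),
        hr_grid_from_ci(params.treatment_effects[drug], cfg.threshold_step),
        lambda hr: runner.outcomes(3, hr_3v6_override=hr),
        cfg.wtp,
    )
    written = render_report({f"threshold_{drug}": curve}, cfg, cfg.output_dir)
    click.echo(
        f"{drug}: first HR with QALY loss {curve.first_hr_qaly_loss}, "
        f"first HR not cost effective {curve.first_hr_not_cost_effective}"
    )
    click.echo(f"wrote {len(written)} files to {cfg.output_dir}")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--bound", type=click.Choice(["lower", "upper"]), required=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "output_dir", type=click.Path(file_okay=False), default="results")
def oneway(config_path, bound, seed, output_dir) -> None:
    """One-way utility analysis at a confidence-interval bound."""
    cfg = _load_config(config_path, seed=seed, output_dir=output_dir)
    params = cfg.load_parameters()
    rows = []
    for drug in cfg.drugs:
        runner = ModelRunner(
            params, drug, cfg.horizon, cfg.half_cycle, cfg.quit_fraction_incurred,
            cfg.survivor_cc_hazard,
        )
        res = oneway_utilities(bound, lambda d, b: runner.outcomes(d, utility_bound=b), cfg.wtp)
        for label in ("6m", "3m"):
            row = endpoint_row(drug, int(label[0]), res[label])
            row["bound"] = bound
            rows.append(row)
        rows[-1]["inmb_vs_6m"] = res["comparison"].inmb
    written = render_report({"oneway": pd.DataFrame(rows)}, cfg, cfg.output_dir)
    click.echo(f"wrote {len(written)} files to {cfg.output_dir}")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--drug", type=click.Choice(DRUGS), required=True)
@click.option("--n", "n_psa", type=int, default=1000, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "output_dir", type=click.Path(file_okay=False), default="results")
@click.option("--plot/--no-plot", default=False, help="Also write CE-plane and CEAC figures.")
def psa(config_path, drug, n_psa, seed, output_dir, plot) -> None:
    """Probabilistic sensitivity analysis: CE plane and acceptability curve."""
    cfg = _load_config(config_path, seed=seed, output_dir=output_dir, n_psa=n_psa, drugs=(drug,))
    params = cfg.load_parameters()
    result = run_psa(
        params,
        drug,
        n=cfg.n_psa,
        seed=cfg.seed,
        horizon=cfg.horizon,
        quit_fraction_incurred=cfg.quit_fraction_incurred,
        survivor_cc_hazard=cfg.survivor_cc_hazard,
        wtp=cfg.wtp,
    )
    written = render_report({f"psa_{drug}": result}, cfg, cfg.output_dir)
    if plot:
        written.update(_psa_plots(result, drug, Path(cfg.output_dir)))
    p3 = result.ceac.probability("3m", cfg.wtp)
    click.echo(f"{drug}: P(3m has highest NMB at WTP {cfg.wtp:.0f}) = {p3:.3f}")
    click.echo(f"wrote {len(written)} files to {cfg.output_dir}")


def _psa_plots(result, drug: str, out: Path) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = {}
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.ce_plane["delta_qaly"], result.ce_plane["delta_cost"], s=4, alpha=0.4)
    ax.axhline(0, lw=0.6, color="k")
    ax.axvline(0, lw=0.6, color="k")
    ax.set_xlabel("Incremental QALYs (3m - 6m)")
    ax.set_ylabel("Incremental costs, EUR (3m - 6m)")
    ax.set_title(f"{drug}: cost-effectiveness plane")
    path = out / f"ce_plane_{drug}.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written[f"ce_plane_{drug}_plot"] = path
    fig, ax = plt.subplots(figsize=(5, 4))
    for j, label in enumerate(result.ceac.strategy_labels):
        ax.plot(result.ceac.lambda_grid, result.ceac.probabilities[:, j], label=label)
    ax.set_xlabel("Willingness to pay, EUR/QALY")
    ax.set_ylabel("P(highest NMB)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    ax.set_title(f"{drug}: acceptability curves")
    path = out / f"ceac_{drug}.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written[f"ceac_{drug}_plot"] = path
    return written
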