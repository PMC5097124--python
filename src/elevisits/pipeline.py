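"""End-to-end orchestration: fit, counterfactual, valuation, cost/ROI.

The stages mirror the study workflow: (1) Bayesian estimation of the
visitation model on PAs with visitor data; (2) predicted visits at every
elephant-holding PA without poaching; (3) the same with densities reduced by
the poaching decline rates; (4) Monte Carlo valuation of the visit losses;
plus the anti-poaching cost/ROI assessment for large elephant populations.
All randomness is driven by the seeds in the configuration, so a fixed
config and inputs reproduce the report byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .counterfactual import (CounterfactualResult, aggregate_visit_losses,
                             counterfactual_all, results_table)
from .io import PARecord, SpendEstimateSet, read_pa_table, read_spend_estimates
from .model import ConvergenceReport, PosteriorFit, check_convergence, fit_visitation_model
from .roi import CostAssessment, assess_costs
from .valuation import (ValuationSummary, fit_spend_distributions,
                        simulate_valuation)


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage name."""


@dataclass
class PipelineReport:
    config: dict
    convergence: dict
    coefficients: pd.DataFrame = field(repr=False)
    counterfactual: pd.DataFrame = field(repr=False)
    visit_loss_by_region: pd.DataFrame = field(repr=False)
    valuation_by_region: pd.DataFrame = field(repr=False)
    cost_by_region: pd.DataFrame = field(repr=False)
    headline: dict
    seeds: dict

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seeds": self.seeds,
            "convergence": self.convergence,
            "coefficients": self.coefficients.to_dict(orient="records"),
            "counterfactual": self.counterfactual.to_dict(orient="records"),
            "visit_loss_by_region": self.visit_loss_by_region.to_dict(orient="records"),
            "valuation_by_region": self.valuation_by_region.to_dict(orient="records"),
            "cost_by_region": self.cost_by_region.to_dict(orient="records"),
            "headline": self.headline,
        }


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc
        return wrapped
    return deco


def run_pipeline_from_objects(records: Sequence[PARecord],
                              estimates: SpendEstimateSet,
                              config: Optional[PipelineConfig] = None,
                              ) -> PipelineReport:
    """Run all stages on in-memory inputs; see :func:`run_pipeline`."""
    config = config or PipelineConfig()

    fit: PosteriorFit = _stage("fit")(fit_visitation_model)(records, config)
    conv: ConvergenceReport = _stage("convergence")(check_convergence)(fit, config)
    cf: list[CounterfactualResult] = _stage("counterfactual")(counterfactual_all)(fit, records)
    by_region = _stage("counterfactual")(aggregate_visit_losses)(cf)

    dist = _stage("valuation")(fit_spend_distributions)(estimates)
    seed_all, seed_large = (int(s) for s in
                            np.random.SeedSequence(config.valuation.seed)
                            .generate_state(2) % (2**31))
    val: ValuationSummary = _stage("valuation")(simulate_valuation)(
        cf, dist, config.valuation.n_draws, seed_all)

    threshold = config.cost.large_pop_threshold
    large_cf = [r for r in cf if r.elephant_pop_mean > threshold]
    if large_cf:
        val_large = _stage("valuation")(simulate_valuation)(
            large_cf, dist, config.valuation.n_draws, seed_large)
        benefits = {row["region"]: row["total_mean"]
                    for row in val_large.per_region.to_dict(orient="records")}
    else:
        benefits = {}
    costs: CostAssessment = _stage("roi")(assess_costs)(records, benefits, config.cost)

    headline = {
        "total_visit_loss": val.overall["visit_loss"],
        "direct_loss_usd": val.overall["direct"],
        "indirect_loss_usd": val.overall["indirect"],
        "total_loss_usd": val.overall["total"],
        "n_pas_fit": int(sum(r.visits is not None for r in records)),
        "n_pas_counterfactual": len(cf),
        "n_pas_large": len(large_cf),
    }
    return PipelineReport(
        config=config.model_dump(mode="json"),
        convergence=conv.to_dict(),
        coefficients=fit.summary(),
        counterfactual=results_table(cf),
        visit_loss_by_region=by_region,
        valuation_by_region=val.per_region,
        cost_by_region=costs.per_region,
        headline=headline,
        seeds={"mcmc": config.mcmc.seed, "valuation": config.valuation.seed,
               "valuation_all_pas": seed_all, "valuation_large_pas": seed_large},
    )


def run_pipeline(config: PipelineConfig, pa_path, spend_direct_path,
                 spend_mult_path) -> PipelineReport:
    """Read inputs from disk and run the full pipeline."""
    records = _stage("read")(read_pa_table)(pa_path)
    estimates = _stage("read")(read_spend_estimates)(spend_direct_path, spend_mult_path)
    return run_pipeline_from_objects(records, estimates, config)


def render_report(report: PipelineReport, fmt: str, out_dir) -> list[Path]:
    """Write the report as text, delimited tables or JSON; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt == "json":
        path = out_dir / "report.json"
        path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        written.append(path)
    elif fmt == "delimited":
        tables = {
            "coefficients.csv": report.coefficients,
            "counterfactual.csv": report.counterfactual,
            "visit_loss_by_region.csv": report.visit_loss_by_region,
            "valuation_by_region.csv": report.valuation_by_region,
            "cost_by_region.csv": report.cost_by_region,
        }
        for name, df in tables.items():
            path = out_dir / name
            df.to_csv(path, index=False)
            written.append(path)
        path = out_dir / "headline.json"
        path.write_text(json.dumps(
            {"headline": report.headline, "seeds": report.seeds,
             "convergence": {k: v for k, v in report.convergence.items()
                             if k != "parameters"}},
            indent=2, sort_keys=True))
        written.append(path)
    elif fmt == "text":
        lines = ["elevisits pipeline report", "=" * 60, "",
                 "Coefficients (posterior mean, sd, 2.5%, 97.5%, ESS, R-hat)",
                 report.coefficients.to_string(index=False), "",
                 "Visit losses by region",
                 report.visit_loss_by_region.to_string(index=False), "",
                 "Valuation by region (USD 2016)",
                 report.valuation_by_region.to_string(index=False), "",
                 "Costs and rates of return by region",
                 report.cost_by_region.to_string(index=False), "",
                 "Headline: " + json.dumps(report.headline, sort_keys=True),
                 "Seeds: " + json.dumps(report.seeds, sort_keys=True),
                 "Convergence pass: " + str(report.convergence["pass"])]
        path = out_dir / "report.txt"
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected text, delimited or json)")
    return written
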