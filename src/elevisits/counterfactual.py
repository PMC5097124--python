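"""Poaching counterfactual: predicted visits with and without the
poaching-driven reduction in elephant density, per PA and aggregated.

Both arms hold non-density covariates at their fit-data means; the baseline
density is the census mean divided by the censused area and the poached arm
scales it by (1 - annual decline rate). The visit loss is the difference of
posterior-predictive medians, floored at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io import REGIONS, PARecord
from .model import PosteriorFit, predict_visits

logger = logging.getLogger("elevisits.counterfactual")


def poached_density(density: float, decline_rate: float) -> float:
    """Density after one year of poaching at an annual proportional loss."""
    if not (0.0 <= decline_rate < 1.0):
        raise ValueError("decline_rate must be in [0, 1)")
    if density < 0:
        raise ValueError("density must be nonnegative")
    return density * (1.0 - decline_rate)


@dataclass
class CounterfactualResult:
    pa_id: str
    region: str
    baseline_density: float
    reduced_density: float
    median_visits_baseline: float
    median_visits_reduced: float
    visit_loss: float
    elephant_pop_mean: float


def visit_loss(fit: PosteriorFit, record: PARecord) -> CounterfactualResult:
    """Median annual visits lost at one PA due to its poaching decline rate."""
    if record.elephant_pop_mean is None:
        raise ValueError(f"pa_id={record.pa_id!r}: no elephant population")
    base_d = record.observed_density
    red_d = poached_density(base_d, record.poach_decline_rate)
    base = predict_visits(fit, base_d, forest=record.forest)
    red = predict_visits(fit, red_d, forest=record.forest)
    loss = base.median - red.median
    if loss < 0:
        logger.info("pa_id=%s: negative visit loss %.3f floored at 0", record.pa_id, loss)
        loss = 0.0
    return CounterfactualResult(
        pa_id=record.pa_id,
        region=record.region,
        baseline_density=base_d,
        reduced_density=red_d,
        median_visits_baseline=base.median,
        median_visits_reduced=red.median,
        visit_loss=loss,
        elephant_pop_mean=record.elephant_pop_mean,
    )


def counterfactual_all(fit: PosteriorFit,
                       records: Sequence[PARecord]) -> list[CounterfactualResult]:
    """Visit losses for every record holding elephants."""
    return [visit_loss(fit, r) for r in records if r.elephant_pop_mean is not None]


def aggregate_visit_losses(results: Sequence[CounterfactualResult]) -> pd.DataFrame:
    """Per-region visit-loss totals plus an overall row (region = 'all').

    The grand total is exactly the sum of the regional totals.
    """
    if not results:
        raise ValueError("no counterfactual results to aggregate")
    for r in results:
        if r.region not in REGIONS:
            raise ValueError(f"unknown region {r.region!r} for pa_id={r.pa_id!r}")
    ordered = sorted(results, key=lambda r: r.pa_id)  # permutation-invariant sums
    rows = []
    for region in REGIONS:
        sub = [r for r in ordered if r.region == region]
        rows.append({"region": region, "n_pas": len(sub),
                     "visit_loss": float(sum(r.visit_loss for r in sub)),
                     "baseline_visits": float(sum(
                         r.median_visits_baseline for r in sub))})
    total = {"region": "all", "n_pas": len(results),
             "visit_loss": float(sum(r["visit_loss"] for r in rows)),
             "baseline_visits": float(sum(r["baseline_visits"] for r in rows))}
    return pd.DataFrame(rows + [total])


def results_table(results: Sequence[CounterfactualResult]) -> pd.DataFrame:
    """Tidy per-PA counterfactual table."""
    return pd.DataFrame([r.__dict__ for r in results])
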