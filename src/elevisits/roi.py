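"""Anti-poaching spending shortfalls and regional return on investment.

The cost side rests on a 1980s cross-country regression of elephant
population change against per-km^2 conservation expenditure, applicable to
populations over 1,000 animals: zero decline requires $215 km^-2 in 1981 USD,
$565 km^-2 after CPI inflation to 2016. This module adopts a one-parameter
log-spend growth model anchored exactly at that calibration point,

    growth(s) = b * (ln s - ln 565),

so that implied current spend is 565 * exp(growth / b). The annual shortfall
at a PA is max(0, 565 - current spend) x PA area, and the regional rate of
return is 100 x (benefits - costs) / costs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .config import CostConfig
from .io import REGIONS, PARecord

logger = logging.getLogger("elevisits.roi")


class BelowThreshold(Exception):
    """Signal (not an error): the PA's population is at or below the
    large-population threshold the cost model applies to."""


def inflate_benchmark(amount_usd: float, factor: float) -> float:
    """Scale a dollar amount by a configured inflation factor."""
    if amount_usd <= 0 or factor <= 0:
        raise ValueError("amount and factor must be positive")
    return amount_usd * factor


def benchmark_2016(params: Optional[CostConfig] = None) -> float:
    p = params or CostConfig()
    return inflate_benchmark(p.benchmark_1981_usd, p.inflation_factor)


def spend_from_growth(growth_rate: float, params: Optional[CostConfig] = None) -> float:
    """Implied current conservation spend (USD 2016 km^-2) at an annual
    population growth rate, inverting the anchored log-spend model."""
    p = params or CostConfig()
    return benchmark_2016(p) * math.exp(growth_rate / p.slope_b)


def growth_from_spend(spend: float, params: Optional[CostConfig] = None) -> float:
    """Forward model: annual population growth at a given per-km^2 spend."""
    p = params or CostConfig()
    if spend <= 0:
        raise ValueError("spend must be positive")
    return p.slope_b * (math.log(spend) - math.log(benchmark_2016(p)))


def spending_shortfall(record: PARecord, params: Optional[CostConfig] = None) -> float:
    """Annual USD shortfall to reach the zero-decline benchmark at one PA.

    Current spend is the record's reported value when present, otherwise it
    is inferred from the poaching decline rate (growth = -decline). Raises
    :class:`BelowThreshold` for populations at or below the threshold.
    """
    p = params or CostConfig()
    pop = record.elephant_pop_mean or 0.0
    if pop <= p.large_pop_threshold:
        logger.info("pa_id=%s: population %.0f <= threshold %.0f, skipped",
                    record.pa_id, pop, p.large_pop_threshold)
        raise BelowThreshold(record.pa_id)
    if record.current_spend_km2 is not None:
        current = record.current_spend_km2
    else:
        current = spend_from_growth(-record.poach_decline_rate, p)
    return max(0.0, benchmark_2016(p) - current) * record.area_km2


def rate_of_return(total_benefit: float, total_cost: float) -> float:
    """Percent return: 100 x (benefit - cost) / cost."""
    if total_cost <= 0:
        raise ValueError("total_cost must be positive")
    if total_benefit < 0:
        raise ValueError("total_benefit must be nonnegative")
    return 100.0 * (total_benefit - total_cost) / total_cost


@dataclass
class CostAssessment:
    """Per-PA shortfalls and regional cost/benefit/ROI table."""

    per_pa: pd.DataFrame
    per_region: pd.DataFrame


def assess_costs(records: Sequence[PARecord],
                 regional_benefits: dict[str, float],
                 params: Optional[CostConfig] = None) -> CostAssessment:
    """Shortfalls for PAs above the population threshold and regional ROI.

    ``regional_benefits`` maps region -> mean annual lost tourism benefit
    (USD) at the same large-population PAs.
    """
    p = params or CostConfig()
    rows = []
    for rec in records:
        try:
            sf = spending_shortfall(rec, p)
        except BelowThreshold:
            continue
        current = (rec.current_spend_km2 if rec.current_spend_km2 is not None
                   else spend_from_growth(-rec.poach_decline_rate, p))
        rows.append({"pa_id": rec.pa_id, "region": rec.region,
                     "elephant_pop_mean": rec.elephant_pop_mean,
                     "implied_current_spend_km2": current,
                     "shortfall_usd": sf})
    per_pa = pd.DataFrame(rows, columns=["pa_id", "region", "elephant_pop_mean",
                                         "implied_current_spend_km2", "shortfall_usd"])
    region_rows = []
    for region in REGIONS:
        cost = float(per_pa.loc[per_pa["region"] == region, "shortfall_usd"].sum())
        benefit = float(regional_benefits.get(region, 0.0))
        roi = rate_of_return(benefit, cost) if cost > 0 else float("nan")
        region_rows.append({"region": region,
                            "n_pas": int((per_pa["region"] == region).sum()),
                            "total_cost_usd": cost,
                            "total_benefit_usd": benefit,
                            "rate_of_return_percent": roi})
    return CostAssessment(per_pa=per_pa, per_region=pd.DataFrame(region_rows))
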