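"""Validation-trial scoring: per cent achievement, response ratio, BCR.

A targeted-yield prescription is judged by whether the harvested yield lands
within +-10% of the target (per cent achievement), by the yield response per
kg of fertilizer nutrient applied (response ratio, against the untreated
absolute control), and by the benefit-cost ratio when prices are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: accepted half-width of the achievement window, per cent of target
ACHIEVEMENT_WINDOW_PCT = 10.0


def percent_achievement(yield_obtained: float, target: float) -> float:
    """Harvested yield as a percentage of the target (same units for both)."""
    if target is None or not target > 0:
        raise ValueError("yield target must be positive")
    return 100.0 * yield_obtained / target


def within_achievement_window(
    pct: float, window_pct: float = ACHIEVEMENT_WINDOW_PCT
) -> bool:
    """True when achievement lies within the accepted +-window of 100%."""
    return abs(pct - 100.0) <= window_pct


def response_ratio(
    yield_t_ha: float,
    control_yield_t_ha: float,
    doses_kg_ha: Sequence[float],
) -> float:
    """Yield response over the absolute control per kg of fertilizer nutrient.

    ``(yield - control) in kg/ha`` divided by the summed N + P2O5 + K2O doses;
    manure mass is not part of the denominator.  Undefined (NaN) for an
    unfertilized treatment.
    """
    total = float(np.sum(doses_kg_ha))
    if total < 0:
        raise ValueError("doses must be non-negative")
    if total == 0:
        return float("nan")
    return (yield_t_ha - control_yield_t_ha) * 1000.0 / total


def percent_increase_over_control(mean_treated: float, mean_control: float) -> float:
    """Percentage increase of a treated mean over the control mean."""
    if mean_control <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (mean_treated - mean_control) / mean_control


def benefit_cost_ratio(
    yield_t_ha: float,
    produce_price_per_kg: float,
    doses_kg_ha: Sequence[float],
    nutrient_costs_per_kg: Sequence[float],
    fym_t_ha: float = 0.0,
    fym_price_per_t: float = 0.0,
    fixed_cost: float = 0.0,
) -> float:
    """Gross return divided by total cost of cultivation.

    Gross = yield * produce price; cost = fixed cost + sum(dose * unit cost)
    + manure cost.  Any consistent currency works; the ratio is unitless.
    """
    cost = (
        fixed_cost
        + float(np.dot(doses_kg_ha, nutrient_costs_per_kg))
        + fym_t_ha * fym_price_per_t
    )
    if cost <= 0:
        raise ValueError("total cost must be positive")
    return yield_t_ha * 1000.0 * produce_price_per_kg / cost


@dataclass
class PriceCalibration:
    """Prices implied by two published BCR rows (fixed cost normalized to 1).

    ``feasible`` is False when the implied per-kg nutrient cost is negative,
    i.e. the published BCR column cannot arise from any shared fixed cost
    plus non-negative input costs — in that case absolute BCRs are not
    reproducible and only the helper's record of the implied values remains.
    """

    produce_price_per_kg: float
    nutrient_cost_per_kg: float
    fixed_cost: float
    feasible: bool


def calibrate_prices(
    control_yield_t_ha: float,
    control_bcr: float,
    treated_yield_t_ha: float,
    treated_bcr: float,
    treated_total_dose_kg: float,
) -> PriceCalibration:
    """Back-solve produce price and a uniform per-kg nutrient cost from an
    unfertilized control row and one fertilized row (fixed cost = 1)."""
    if min(control_yield_t_ha, control_bcr, treated_yield_t_ha, treated_bcr) <= 0:
        raise ValueError("yields and BCRs must be positive")
    if treated_total_dose_kg <= 0:
        raise ValueError("the treated row must carry a positive total dose")
    price = control_bcr / (control_yield_t_ha * 1000.0)
    unit_cost = (treated_yield_t_ha * 1000.0 * price / treated_bcr - 1.0) / treated_total_dose_kg
    return PriceCalibration(
        produce_price_per_kg=price,
        nutrient_cost_per_kg=unit_cost,
        fixed_cost=1.0,
        feasible=unit_cost >= 0,
    )


def score_validation(
    records: pd.DataFrame,
    control_treatment: str = "absolute_control",
    prices: dict | None = None,
) -> pd.DataFrame:
    """Score a validation table: achievement, window flag, response ratio.

    ``records`` follows the validation schema (treatment, fym_t_ha, doses,
    yield_t_ha, target_t_ha).  The response baseline is the absolute-control
    row.  With a ``prices`` dict (produce_price_per_kg, nutrient_costs_per_kg,
    fym_price_per_t, fixed_cost) a BCR column is added.
    """
    ctrl = records[records["treatment"] == control_treatment]
    if len(ctrl) != 1:
        raise ValueError(f"expected exactly one {control_treatment!r} row")
    control_yield = float(ctrl["yield_t_ha"].iloc[0])
    out = records.copy()
    dose_cols = ["f_n", "f_p2o5", "f_k2o"]
    achievement, in_window, rr = [], [], []
    for _, row in records.iterrows():
        target = row["target_t_ha"]
        if pd.isna(target) or target is None:
            achievement.append(np.nan)
            in_window.append(None)
        else:
            pct = percent_achievement(row["yield_t_ha"], float(target))
            achievement.append(round(pct, 1))
            in_window.append(within_achievement_window(pct))
        rr.append(
            response_ratio(row["yield_t_ha"], control_yield, row[dose_cols].to_numpy(float))
        )
    out["achievement_pct"] = achievement
    out["within_window"] = in_window
    out["response_ratio_kg_per_kg"] = np.round(rr, 2)
    out["pct_increase_over_control"] = np.round(
        [
            percent_increase_over_control(y, control_yield) if y != control_yield else 0.0
            for y in records["yield_t_ha"]
        ],
        2,
    )
    if prices is not None:
        out["bcr"] = [
            round(
                benefit_cost_ratio(
                    row["yield_t_ha"],
                    prices["produce_price_per_kg"],
                    row[dose_cols].to_numpy(float),
                    prices["nutrient_costs_per_kg"],
                    row["fym_t_ha"],
                    prices.get("fym_price_per_t", 0.0),
                    prices.get("fixed_cost", 0.0),
                ),
                2,
            )
            for _, row in records.iterrows()
        ]
    return out
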