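"""Basic parameters of the targeted-yield model.

The inductive soil-test crop response (STCR) method condenses a
fertility-gradient trial into four "basic parameters" per nutrient:

``NR``
    nutrient requirement, kg of nutrient taken up per quintal (100 kg) of
    economic produce.  Expressed on the oxide basis for P and K
    (P2O5, K2O), as fertilizer schedules are.
``Cs``
    per cent contribution of the soil's available pool to total uptake,
    on the element basis: 100 * uptake / soil-test value, from unfertilized,
    unmanured control plots.
``Cf``
    per cent contribution of fertilizer to uptake, on the oxide basis:
    the uptake gain over the soil contribution per kg of oxide applied,
    from fertilized plots that received no manure.
``Cfym``
    per cent contribution of farmyard manure, on the element basis:
    the uptake gain over soil + fertilizer contributions per kg of
    elemental nutrient supplied through the manure, from manured plots.

These four numbers are all that is needed to write the fertilizer
prescription equation F = (NR/Cf)*100*T - (Cs/Cf)*S - (Cfym/Cf)*O
(see :mod:`stcr.prescription`).

Estimators average plot-level ratios by default (mean of ratios); a
ratio-of-means variant is available where the aggregate estimate is
preferred.  For nutrient requirement an additional "closure" estimator is
provided that solves the yield-closure identity used by the synthetic trial
generator (the plot yield is the across-nutrient mean of per-nutrient
implied yields); it inverts the generator exactly on noise-free data,
whereas the classical per-plot ratio carries a small aggregation bias
whenever the per-nutrient implied yields differ within a plot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import DOSE_COLUMN, NUTRIENTS, STV_COLUMN, UPTAKE_COLUMN


@dataclass(frozen=True)
class Conversions:
    """Element <-> oxide conversion factors (P -> P2O5, K -> K2O)."""

    p_to_p2o5: float = 2.2914
    k_to_k2o: float = 1.2046

    def __post_init__(self) -> None:
        if self.p_to_p2o5 <= 1 or self.k_to_k2o <= 1:
            raise ValueError("element->oxide conversion factors must exceed 1")

    def factor(self, nutrient: str) -> float:
        """Multiplier taking an element quantity to the oxide basis."""
        return {"n": 1.0, "p2o5": self.p_to_p2o5, "k2o": self.k_to_k2o}[nutrient]


@dataclass
class BasicParameters:
    """Per-nutrient basic parameters (keys ``n``, ``p2o5``, ``k2o``)."""

    nr: dict[str, float]
    cs_pct: dict[str, float]
    cf_pct: dict[str, float]
    cfym_pct: dict[str, float]
    #: per-nutrient count of negative plot-level Cf/Cfym ratios kept in the mean
    diagnostics: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for j in NUTRIENTS:
            if self.nr[j] <= 0:
                raise ValueError(f"NR must be positive, got {self.nr[j]} for {j}")
            for name, d in (("cs", self.cs_pct), ("cf", self.cf_pct), ("cfym", self.cfym_pct)):
                if not np.isfinite(d[j]):
                    raise ValueError(f"{name} for {j} is not finite")

    def to_frame(self) -> pd.DataFrame:
        """Parameter table: rows NR/Cs/Cf/Cfym, columns N/P2O5/K2O."""
        return pd.DataFrame(
            [self.nr, self.cs_pct, self.cf_pct, self.cfym_pct],
            index=["nr_kg_per_q", "cs_pct", "cf_pct", "cfym_pct"],
            columns=list(NUTRIENTS),
        )


class MissingStratumError(ValueError):
    """The plot set lacks a treatment stratum required by an estimator."""


def _is_control(plots: pd.DataFrame) -> pd.Series:
    return (
        (plots["f_n"] == 0)
        & (plots["f_p2o5"] == 0)
        & (plots["f_k2o"] == 0)
        & (plots["fym_t_ha"] == 0)
    )


def _is_fertilized(plots: pd.DataFrame) -> pd.Series:
    return (plots["f_n"] > 0) | (plots["f_p2o5"] > 0) | (plots["f_k2o"] > 0)


def _aggregate(num: np.ndarray, den: np.ndarray, method: str) -> float:
    if method == "mean_of_ratios":
        return float(np.mean(num / den))
    if method == "ratio_of_means":
        return float(np.sum(num) / np.sum(den))
    raise ValueError(f"unknown estimator method: {method!r}")


def nutrient_requirement(
    plots: pd.DataFrame,
    conversions: Conversions = Conversions(),
    method: str = "mean_of_ratios",
) -> dict[str, float]:
    """Nutrient requirement per nutrient, kg (oxide basis) per quintal.

    Per plot ``NR = uptake_element * conv / (yield_kg_ha / 100)``; the mean
    over fertilized plots is returned.  Plots with zero yield are excluded
    with a warning.
    """
    sub = plots[_is_fertilized(plots)]
    if len(sub) == 0:
        raise MissingStratumError("no fertilized stratum")
    bad = sub["yield_kg_ha"] <= 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} plot(s) with non-positive yield")
        sub = sub[~bad]
    if len(sub) == 0:
        raise ValueError("all fertilized plots excluded (zero yield)")
    yield_q = sub["yield_kg_ha"].to_numpy() / 100.0
    return {
        j: _aggregate(
            sub[UPTAKE_COLUMN[j]].to_numpy() * conversions.factor(j), yield_q, method
        )
        for j in NUTRIENTS
    }


def nutrient_requirement_closure(
    plots: pd.DataFrame, conversions: Conversions = Conversions()
) -> dict[str, float]:
    """NR via least squares on the yield-closure identity.

    When the plot yield is the across-nutrient mean of per-nutrient implied
    yields, ``sum_j U_j * conv_j / NR_j = 3 * Y`` holds per plot; solving for
    ``x_j = 1/NR_j`` over fertilized plots recovers NR exactly on noise-free
    data and is near-unbiased under multiplicative uptake noise.
    """
    sub = plots[_is_fertilized(plots) & (plots["yield_kg_ha"] > 0)]
    if len(sub) < len(NUTRIENTS):
        raise MissingStratumError("need at least 3 fertilized plots for closure NR")
    A = np.column_stack(
        [sub[UPTAKE_COLUMN[j]].to_numpy() * conversions.factor(j) for j in NUTRIENTS]
    )
    b = 3.0 * sub["yield_kg_ha"].to_numpy() / 100.0
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.any(x <= 0):
        raise ValueError("closure estimator produced a non-positive 1/NR")
    return {j: float(1.0 / x[i]) for i, j in enumerate(NUTRIENTS)}


def soil_contribution(plots: pd.DataFrame, method: str = "mean_of_ratios") -> dict[str, float]:
    """Per cent soil contribution ``Cs = 100 * uptake / STV`` from control plots."""
    sub = plots[_is_control(plots)]
    if len(sub) == 0:
        raise MissingStratumError("no control stratum")
    out: dict[str, float] = {}
    for j in NUTRIENTS:
        s = sub[STV_COLUMN[j]].to_numpy(dtype=float)
        u = sub[UPTAKE_COLUMN[j]].to_numpy(dtype=float)
        keep = s > 0
        if not keep.all():
            warnings.warn(
                f"excluding {int((~keep).sum())} control plot(s) with zero {STV_COLUMN[j]}"
            )
        if not keep.any():
            raise ValueError(f"no usable control plot for {j}")
        out[j] = _aggregate(100.0 * u[keep], s[keep], method)
    return out


def fertilizer_contribution(
    plots: pd.DataFrame,
    cs_pct: dict[str, float],
    conversions: Conversions = Conversions(),
    method: str = "mean_of_ratios",
) -> tuple[dict[str, float], dict[str, int]]:
    """Per cent fertilizer contribution Cf (oxide basis) and a count of
    negative plot-level ratios (kept in the mean, not truncated).

    Uses fertilized plots without manure, per nutrient those with a positive
    dose of that nutrient:
    ``Cf = 100 * conv * (U - (Cs/100) * S) / F_oxide``.
    """
    sub = plots[(plots["fym_t_ha"] == 0) & _is_fertilized(plots)]
    out: dict[str, float] = {}
    negatives: dict[str, int] = {}
    for j in NUTRIENTS:
        q = sub[sub[DOSE_COLUMN[j]] > 0]
        if len(q) == 0:
            raise MissingStratumError(f"no FYM-free plot fertilized with {j}")
        gain = (
            q[UPTAKE_COLUMN[j]].to_numpy()
            - (cs_pct[j] / 100.0) * q[STV_COLUMN[j]].to_numpy()
        )
        ratios_num = 100.0 * conversions.factor(j) * gain
        negatives[j] = int((ratios_num < 0).sum())
        out[j] = _aggregate(ratios_num, q[DOSE_COLUMN[j]].to_numpy(), method)
    return out, negatives


def fym_contribution(
    plots: pd.DataFrame,
    cs_pct: dict[str, float],
    cf_pct: dict[str, float],
    fym_spec,
    conversions: Conversions = Conversions(),
    method: str = "mean_of_ratios",
) -> tuple[dict[str, float], dict[str, int]]:
    """Per cent manure contribution Cfym (element basis) and negative-ratio counts.

    Uses manured plots; the manure nutrient credit ``O`` (kg/ha, element
    basis) comes from ``fym_spec`` (:class:`stcr.prescription.FymSpec`):
    ``Cfym = 100 * (U - (Cs/100)*S - (Cf/100)*F_oxide/conv) / O``.
    """
    sub = plots[plots["fym_t_ha"] > 0]
    if len(sub) == 0:
        raise MissingStratumError("no FYM stratum")
    rates = sub["fym_t_ha"].to_numpy()
    credits = {rate: fym_spec.credit(rate) for rate in np.unique(rates)}
    out: dict[str, float] = {}
    negatives: dict[str, int] = {}
    o_key = {"n": "o_n", "p2o5": "o_p", "k2o": "o_k"}
    for j in NUTRIENTS:
        o = np.array([getattr(credits[r], o_key[j]) for r in rates])
        if np.any(o <= 0):
            raise ValueError(f"FYM credit for {j} is zero on a manured plot")
        gain = (
            sub[UPTAKE_COLUMN[j]].to_numpy()
            - (cs_pct[j] / 100.0) * sub[STV_COLUMN[j]].to_numpy()
            - (cf_pct[j] / 100.0)
            * sub[DOSE_COLUMN[j]].to_numpy()
            / conversions.factor(j)
        )
        negatives[j] = int((gain < 0).sum())
        out[j] = _aggregate(100.0 * gain, o, method)
    return out, negatives


def estimate_all(
    plots: pd.DataFrame,
    conversions: Conversions = Conversions(),
    fym_spec=None,
    method: str = "mean_of_ratios",
    nr_method: str = "ratio",
) -> BasicParameters:
    """Estimate all basic parameters, staging Cs -> Cf -> Cfym -> NR.

    Parameters
    ----------
    plots : DataFrame
        Plot table containing control, fertilized-unmanured and manured strata.
    method : str
        ``"mean_of_ratios"`` (default) or ``"ratio_of_means"`` aggregation of
        plot-level ratios.
    nr_method : str
        ``"ratio"`` (classical per-plot uptake/yield ratio, default) or
        ``"closure"`` (model-consistent least squares, see
        :func:`nutrient_requirement_closure`).
    """
    if fym_spec is None:
        from .prescription import FymSpec

        fym_spec = FymSpec()
    cs = soil_contribution(plots, method=method)
    cf, neg_cf = fertilizer_contribution(plots, cs, conversions, method=method)
    cfym, neg_cfym = fym_contribution(
        plots, cs, cf, fym_spec, conversions, method=method
    )
    if nr_method == "ratio":
        nr = nutrient_requirement(plots, conversions, method=method)
    elif nr_method == "closure":
        nr = nutrient_requirement_closure(plots, conversions)
    else:
        raise ValueError(f"unknown nr_method: {nr_method!r}")
    return BasicParameters(
        nr=nr,
        cs_pct=cs,
        cf_pct=cf,
        cfym_pct=cfym,
        diagnostics={"negative_cf": neg_cf, "negative_cfym": neg_cfym},
    )
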