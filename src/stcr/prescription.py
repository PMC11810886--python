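"""Fertilizer prescription equations, IPNS dose computation and ready reckoners.

The targeted-yield prescription for each nutrient is linear in the yield
target ``T`` (q/ha), the soil-test value ``S`` (kg/ha, element basis) and the
manure nutrient credit ``O`` (kg/ha, element basis)::

    F = a*T - b*S - c*O          a = NR*100/Cf
                                 b = (Cs/Cf) * conv
                                 c = (Cfym/Cf) * conv

with ``conv`` the element->oxide factor (1 for N).  ``F`` is the fertilizer
dose in kg/ha on the oxide basis.  Doses below a configured maintenance
floor are raised to the floor; doses above the maximum tested level are
capped; a raw negative dose with no floor becomes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .basic_params import BasicParameters, Conversions
from .schema import NUTRIENTS


class Credits(NamedTuple):
    """Manure nutrient credits O (kg/ha, element basis)."""

    o_n: float
    o_p: float
    o_k: float

    def get(self, nutrient: str) -> float:
        return {"n": self.o_n, "p2o5": self.o_p, "k2o": self.o_k}[nutrient]

    def scaled(self, factor: float) -> "Credits":
        return Credits(self.o_n * factor, self.o_p * factor, self.o_k * factor)


@dataclass(frozen=True)
class FymSpec:
    """Farmyard manure composition.

    Percentages are of N, P and K (element basis) in the manure; with
    ``basis="fresh"`` they apply to the as-applied fresh weight, with
    ``basis="dry"`` to dry matter, in which case the credit is discounted
    by the moisture fraction.
    """

    moisture_fraction: float = 0.26
    n_pct: float = 0.56
    p_pct: float = 0.23
    k_pct: float = 0.47
    basis: str = "fresh"

    def __post_init__(self) -> None:
        if not 0 <= self.moisture_fraction < 1:
            raise ValueError("moisture_fraction must be in [0, 1)")
        for pct in (self.n_pct, self.p_pct, self.k_pct):
            if not 0 <= pct <= 100:
                raise ValueError("nutrient percentages must be in [0, 100]")
        if self.basis not in ("fresh", "dry"):
            raise ValueError("basis must be 'fresh' or 'dry'")

    def credit(self, rate_t_ha: float) -> Credits:
        """Nutrient credit (kg/ha) for a manure application rate in t/ha."""
        return fym_nutrient_credit(self, rate_t_ha)


def fym_nutrient_credit(spec: FymSpec, rate_t_ha: float) -> Credits:
    """Quantities of N, P and K supplied through manure, kg/ha element basis."""
    if rate_t_ha < 0:
        raise ValueError("manure rate must be non-negative")
    kg = rate_t_ha * 1000.0
    if spec.basis == "dry":
        kg *= 1.0 - spec.moisture_fraction
    return Credits(kg * spec.n_pct / 100.0, kg * spec.p_pct / 100.0, kg * spec.k_pct / 100.0)


@dataclass(frozen=True)
class NutrientEquation:
    """Prescription coefficients for one nutrient, with dose floor/cap (kg/ha)."""

    a: float
    b: float
    c: float
    floor: float | None = None
    cap: float | None = None

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("equation coefficients must be positive")
        if self.floor is not None and self.cap is not None and self.floor >= self.cap:
            raise ValueError("floor must be below cap")

    def rounded(self, ndigits: int = 2) -> "NutrientEquation":
        """Copy with coefficients at display precision (2 decimals as published)."""
        return replace(
            self, a=round(self.a, ndigits), b=round(self.b, ndigits), c=round(self.c, ndigits)
        )


@dataclass(frozen=True)
class EquationSet:
    """Prescription equations for N, P2O5 and K2O."""

    n: NutrientEquation
    p2o5: NutrientEquation
    k2o: NutrientEquation

    def get(self, nutrient: str) -> NutrientEquation:
        return getattr(self, nutrient)

    def rounded(self, ndigits: int = 2) -> "EquationSet":
        return EquationSet(*(self.get(j).rounded(ndigits) for j in NUTRIENTS))

    def to_frame(self) -> pd.DataFrame:
        rows = {
            j: {
                "a_target": eq.a,
                "b_soil": eq.b,
                "c_fym": eq.c,
                "floor_kg_ha": eq.floor,
                "cap_kg_ha": eq.cap,
            }
            for j in NUTRIENTS
            for eq in [self.get(j)]
        }
        return pd.DataFrame(rows).T


def derive_equation(
    params: BasicParameters,
    conversions: Conversions = Conversions(),
    floors: dict[str, float] | None = None,
    caps: dict[str, float] | None = None,
) -> EquationSet:
    """Derive the prescription equation set from basic parameters.

    Coefficients are stored at full precision; use :meth:`EquationSet.rounded`
    for the 2-decimal published form.
    """
    floors = floors or {}
    caps = caps or {}
    eqs = {}
    for j in NUTRIENTS:
        conv = conversions.factor(j)
        eqs[j] = NutrientEquation(
            a=params.nr[j] * 100.0 / params.cf_pct[j],
            b=params.cs_pct[j] / params.cf_pct[j] * conv,
            c=params.cfym_pct[j] / params.cf_pct[j] * conv,
            floor=floors.get(j),
            cap=caps.get(j),
        )
    return EquationSet(**eqs)


@dataclass(frozen=True)
class Dose:
    """A computed fertilizer dose.

    ``value`` is the constrained dose at full precision, ``raw`` the
    unconstrained linear prediction; ``flag`` is ``"maintenance"`` when the
    floor was applied, ``"maximum"`` when capped, else ``None``.
    """

    value: float
    raw: float
    flag: str | None = None

    @property
    def rounded(self) -> int:
        """Display dose in whole kg/ha."""
        return int(round(self.value))


def compute_dose(
    eq: NutrientEquation, target_q: float, stv: float, fym_credit: float = 0.0
) -> Dose:
    """Evaluate ``a*T - b*S - c*O`` and apply floor/cap constraints."""
    if target_q < 0 or stv < 0 or fym_credit < 0:
        raise ValueError("target, soil-test value and FYM credit must be non-negative")
    raw = eq.a * target_q - eq.b * stv - eq.c * fym_credit
    if eq.floor is not None and raw < eq.floor:
        return Dose(value=float(eq.floor), raw=raw, flag="maintenance")
    if eq.cap is not None and raw > eq.cap:
        return Dose(value=float(eq.cap), raw=raw, flag="maximum")
    return Dose(value=max(raw, 0.0), raw=raw)


def build_reckoner(
    equations: EquationSet,
    nutrient: str,
    target_q: float,
    stv_grid: Sequence[float],
    fym_options: Sequence[tuple[str, Credits]],
) -> pd.DataFrame:
    """Ready-reckoner table for one nutrient over a soil-test grid.

    One row per soil-test value with the inorganic-alone dose and, per manure
    option, the integrated dose plus its per cent reduction over inorganic
    alone.  Reductions use the whole-kg display doses, as printed tables do.
    Flags propagate ("maintenance" floored, "maximum" capped); a zero
    inorganic dose leaves the reduction undefined (NaN) and flags the cell.
    """
    grid = list(stv_grid)
    if not grid:
        raise ValueError("soil-test grid must be non-empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("soil-test grid must be strictly increasing")
    eq = equations.get(nutrient)
    rows = []
    for stv in grid:
        base = compute_dose(eq, target_q, stv)
        row: dict[str, object] = {
            "stv_kg_ha": stv,
            "dose_npk": base.rounded,
            "flag_npk": base.flag or "",
        }
        for label, credits in fym_options:
            ipns = compute_dose(eq, target_q, stv, credits.get(nutrient))
            row[f"dose_{label}"] = ipns.rounded
            flag = ipns.flag or ""
            if base.rounded == 0:
                reduction = np.nan
                flag = (flag + "|" if flag else "") + "undefined-reduction"
            else:
                reduction = 100.0 * (base.rounded - ipns.rounded) / base.rounded
            row[f"flag_{label}"] = flag
            row[f"reduction_{label}_pct"] = round(float(reduction), 1)
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["nutrient"] = nutrient
    out.attrs["target_q"] = target_q
    return out


def format_reckoner(table: pd.DataFrame) -> str:
    """Aligned-text rendering with asterisks on maintenance/maximum cells."""
    disp = table.copy()
    for col in [c for c in disp.columns if c.startswith("dose_")]:
        flag_col = "flag_" + col[len("dose_"):]
        stars = disp[flag_col].map(
            lambda f: "*" if "maintenance" in f else ("**" if "maximum" in f else "")
        )
        disp[col] = disp[col].astype(str) + stars
    disp = disp.drop(columns=[c for c in disp.columns if c.startswith("flag_")])
    return disp.to_string(index=False)
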