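"""Synthetic fertility-gradient trial generator.

Emulates the three-phase inductive field experiment from known ground-truth
parameters so that every downstream stage — descriptive statistics, basic
parameter estimation, prescription equations, validation scoring — is
testable without field data.

Structure emulated
------------------
* three fertility strips with distinct soil-test means (the legacy of a
  graded-fertilization exhaust crop),
* a 24-treatment fractional factorial of 4 N x 4 P2O5 x 4 K2O dose levels
  with three control replicates per strip,
* three farmyard-manure sub-strips (0 / 6.25 / 12.5 t/ha) superimposed on
  each strip; the three controls always fall in the unmanured sub-strip so
  that control plots receive neither fertilizer nor manure.

Generative model (per plot)
---------------------------
Soil-test values are drawn independently per nutrient from per-strip
truncated normals.  Uptake is composed from contribution fractions::

    U_j = (Cs_j/100) * S_j + (Cf_j/100) * F_j/conv_j + (Cfym_j/100) * O_j

(element basis; ``F`` oxide dose, ``O`` manure credit), then multiplied by
log-normal noise of the configured relative SD.  The fresh yield is the
across-nutrient mean of the per-nutrient implied yields ``U_j*conv_j/NR_j``
(quintals), times its own log-normal noise.  A mean rather than a Liebig
minimum keeps every nutrient informative about NR on every plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .basic_params import Conversions
from .prescription import Credits, EquationSet, FymSpec, compute_dose
from .schema import NUTRIENTS, PLOT_COLUMNS, VALIDATION_COLUMNS

#: dose levels (kg/ha) of the reference factorial
DEFAULT_LEVELS = {
    "n": (0.0, 60.0, 120.0, 180.0),
    "p2o5": (0.0, 80.0, 160.0, 240.0),
    "k2o": (0.0, 50.0, 100.0, 150.0),
}
DEFAULT_FYM_LEVELS = (0.0, 6.25, 12.5)

#: the 24-treatment matrix as (N, P2O5, K2O) level indices; the first three
#: rows are the control replicates
DEFAULT_TREATMENT_MATRIX = (
    (0, 0, 0), (0, 0, 0), (0, 0, 0),
    (0, 2, 2),
    (1, 1, 1), (1, 2, 1), (1, 1, 2), (1, 2, 2),
    (2, 1, 1), (2, 0, 2), (2, 1, 2), (2, 2, 2), (2, 2, 1), (2, 2, 0),
    (2, 2, 3), (2, 3, 2), (2, 3, 3),
    (3, 1, 1), (3, 2, 1), (3, 2, 2), (3, 3, 1), (3, 3, 2), (3, 2, 3), (3, 3, 3),
)


@dataclass(frozen=True)
class TrialDesign:
    """Layout of the test-crop experiment."""

    n_strips: int = 3
    levels: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_LEVELS)
    )
    fym_levels: tuple[float, ...] = DEFAULT_FYM_LEVELS
    treatment_matrix: tuple[tuple[int, int, int], ...] = DEFAULT_TREATMENT_MATRIX

    def __post_init__(self) -> None:
        if self.n_strips < 1:
            raise ValueError("need at least one strip")
        for j in NUTRIENTS:
            lv = self.levels[j]
            if any(v < 0 for v in lv) or any(b <= a for a, b in zip(lv, lv[1:])):
                raise ValueError(f"{j} levels must be non-negative and strictly increasing")
        if any(b <= a for a, b in zip(self.fym_levels, self.fym_levels[1:])):
            raise ValueError("FYM levels must be strictly increasing")
        n_controls = sum(1 for t in self.treatment_matrix if t == (0, 0, 0))
        if len(self.treatment_matrix) != 24 or n_controls != 3:
            raise ValueError("treatment matrix must have 24 rows incl. exactly 3 controls")

    def doses(self, treatment: tuple[int, int, int]) -> tuple[float, float, float]:
        return tuple(self.levels[j][treatment[i]] for i, j in enumerate(NUTRIENTS))


@dataclass(frozen=True)
class GroundTruth:
    """True parameters behind a synthetic trial.

    Defaults reproduce the reference beetroot/ultisol calibration: basic
    parameters from the published table, strip soil-test means from the
    pre-sowing survey and CVs from the gradient field statistics.  Noise CVs
    are relative SDs of the multiplicative log-normal noise on uptake and
    yield (0.05 = 5%, a tight, well-managed trial).
    """

    nr: dict[str, float] = field(default_factory=lambda: dict(reference.BASIC_PARAMETERS.nr))
    cs_pct: dict[str, float] = field(
        default_factory=lambda: dict(reference.BASIC_PARAMETERS.cs_pct)
    )
    cf_pct: dict[str, float] = field(
        default_factory=lambda: dict(reference.BASIC_PARAMETERS.cf_pct)
    )
    cfym_pct: dict[str, float] = field(
        default_factory=lambda: dict(reference.BASIC_PARAMETERS.cfym_pct)
    )
    stv_means: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(reference.STRIP_STV_MEANS)
    )
    stv_cvs_pct: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(reference.STRIP_STV_CVS_PCT)
    )
    uptake_noise_cv: float = 0.05
    yield_noise_cv: float = 0.05
    fym: FymSpec = field(default_factory=FymSpec)
    conversions: Conversions = field(default_factory=Conversions)
    seed: int = 20230901

    def __post_init__(self) -> None:
        for j in NUTRIENTS:
            if self.nr[j] <= 0:
                raise ValueError(f"NR must be positive for {j}")
            for d in (self.cs_pct, self.cf_pct, self.cfym_pct):
                if not 0 < d[j] <= 100:
                    raise ValueError(f"contribution fractions must be in (0, 100] for {j}")
            if any(cv < 0 for cv in self.stv_cvs_pct[j]):
                raise ValueError(f"soil-test CVs must be non-negative for {j}")
        if self.uptake_noise_cv < 0 or self.yield_noise_cv < 0:
            raise ValueError("noise CVs must be non-negative")


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative noise with relative SD ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size))


def _draw_stv(rng: np.random.Generator, mean: float, cv_pct: float) -> float:
    """Normal draw truncated at zero (rejection; effectively never triggers
    at field-realistic CVs)."""
    sd = mean * cv_pct / 100.0
    x = rng.normal(mean, sd)
    while x <= 0:
        x = rng.normal(mean, sd)
    return float(x)


def generate_trial(
    design: TrialDesign = TrialDesign(),
    truth: GroundTruth = GroundTruth(),
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate one synthetic test-crop trial as a plot table.

    Returns ``design.n_strips * 24`` rows in the plot schema.  A fixed seed
    (``truth.seed`` unless overridden) gives a byte-identical table.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n_treat = len(design.treatment_matrix)
    controls = [i for i, t in enumerate(design.treatment_matrix) if t == (0, 0, 0)]
    fertilized = [i for i in range(n_treat) if i not in controls]
    block = n_treat // len(design.fym_levels)

    rows = []
    plot_id = 0
    for strip in range(1, design.n_strips + 1):
        # controls lead the unmanured sub-strip so they get neither input;
        # the 21 fertilized treatments are randomized across the remainder
        layout = controls + list(rng.permutation(fertilized))
        for pos, t_idx in enumerate(layout):
            plot_id += 1
            fym_rate = design.fym_levels[pos // block]
            f_ox = dict(zip(NUTRIENTS, design.doses(design.treatment_matrix[t_idx])))
            o = truth.fym.credit(fym_rate)
            stv, uptake = {}, {}
            for j in NUTRIENTS:
                stv[j] = _draw_stv(
                    rng, truth.stv_means[j][strip - 1], truth.stv_cvs_pct[j][strip - 1]
                )
                conv = truth.conversions.factor(j)
                uptake[j] = (
                    truth.cs_pct[j] / 100.0 * stv[j]
                    + truth.cf_pct[j] / 100.0 * f_ox[j] / conv
                    + truth.cfym_pct[j] / 100.0 * o.get(j)
                )
            u_noise = _lognormal_factors(rng, truth.uptake_noise_cv, len(NUTRIENTS))
            for i, j in enumerate(NUTRIENTS):
                uptake[j] *= u_noise[i]
            yield_q = float(
                np.mean(
                    [uptake[j] * truth.conversions.factor(j) / truth.nr[j] for j in NUTRIENTS]
                )
            )
            yield_kg = 100.0 * yield_q * _lognormal_factors(rng, truth.yield_noise_cv, 1)[0]
            rows.append(
                (
                    plot_id,
                    strip,
                    fym_rate,
                    f_ox["n"],
                    f_ox["p2o5"],
                    f_ox["k2o"],
                    stv["n"],
                    stv["p2o5"],
                    stv["k2o"],
                    yield_kg,
                    uptake["n"],
                    uptake["p2o5"],
                    uptake["k2o"],
                )
            )
    return pd.DataFrame(rows, columns=list(PLOT_COLUMNS))


def generate_validation_trial(
    equations: EquationSet,
    truth: GroundTruth = GroundTruth(),
    targets_t_ha: tuple[float, ...] = (35.0, 40.0, 45.0),
    seed: int | None = None,
    stv: dict[str, float] | None = None,
    noise_cv: float | None = None,
) -> pd.DataFrame:
    """Generate validation-trial records around the prescription equations.

    One record per treatment in the reference layout: general recommended
    dose with and without manure, a targeted-yield inorganic and integrated
    (12.5 t/ha manure) prescription per target, farmer's practice, and an
    absolute control — ten records for three targets.  Targeted treatments
    yield their target times noise; the rest yield the reference baseline
    means times noise.  Doses come from ``equations`` at the validation
    field's soil-test values (default: mean of the strip means).
    """
    targets = tuple(targets_t_ha)
    if not targets or any(t <= 0 for t in targets):
        raise ValueError("yield targets must be a non-empty list of positive values")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    cv = truth.yield_noise_cv if noise_cv is None else noise_cv
    if stv is None:
        stv = {j: float(np.mean(truth.stv_means[j])) for j in NUTRIENTS}
    credit = truth.fym.credit(12.5)
    zero = Credits(0.0, 0.0, 0.0)

    def doses(target_t: float, credits: Credits) -> tuple[float, float, float]:
        return tuple(
            compute_dose(equations.get(j), target_t * 10.0, stv[j], credits.get(j)).value
            for j in NUTRIENTS
        )

    base = reference.BASELINE_YIELDS_T_HA
    rows: list[tuple] = [
        ("gfrd", 0.0, *reference.GFRD_DOSES, base["gfrd"], None),
        ("gfrd_fym", 12.5, *reference.GFRD_DOSES, base["gfrd_fym"], None),
    ]
    for t in targets:
        rows.append((f"stcr_npk_{t:g}t", 0.0, *doses(t, zero), t, t))
    for t in targets:
        rows.append((f"stcr_ipns_{t:g}t", 12.5, *doses(t, credit), t, t))
    rows.append(("ffp", 0.0, *reference.FFP_DOSES, base["ffp"], None))
    rows.append(("absolute_control", 0.0, 0.0, 0.0, 0.0, base["absolute_control"], None))

    df = pd.DataFrame(rows, columns=list(VALIDATION_COLUMNS))
    df["yield_t_ha"] = df["yield_t_ha"].astype(float) * _lognormal_factors(rng, cv, len(df))
    return df
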