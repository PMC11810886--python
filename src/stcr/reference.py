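"""Reference dataset: beetroot on acidic hill ultisols (Nilgiris).

The published field calibration for hill-grown beetroot supplies the default
ground truth for the synthetic trial generator and the worked examples:
basic parameters, the published prescription coefficient set, the strip-wise
soil-test structure of the fertility-gradient field, and the validation
trial records (treatments, doses, harvested yields).

These are inputs to the package, not outputs: everything downstream
(equations, reckoners, validation metrics) is recomputed from them.
"""

from __future__ import annotations

import pandas as pd

from .basic_params import BasicParameters, Conversions
from .prescription import Credits, EquationSet, FymSpec, NutrientEquation
from .schema import VALIDATION_COLUMNS

#: standard element->oxide factors (also implied by the published b/c coefficients)
CONVERSIONS = Conversions(p_to_p2o5=2.2914, k_to_k2o=1.2046)

#: basic parameters for beetroot on the reference ultisol (NR kg/q oxide
#: basis; contributions in per cent)
BASIC_PARAMETERS = BasicParameters(
    nr={"n": 0.38, "p2o5": 0.29, "k2o": 0.46},
    cs_pct={"n": 20.25, "p2o5": 11.02, "k2o": 19.67},
    cf_pct={"n": 55.16, "p2o5": 46.62, "k2o": 56.62},
    cfym_pct={"n": 34.40, "p2o5": 17.46, "k2o": 29.65},
)

#: maintenance floors (kg/ha) implied by the asterisked reckoner cells
DOSE_FLOORS = {"n": 60.0, "k2o": 50.0}
#: maximum doses = highest tested fertilizer levels (kg/ha)
DOSE_CAPS = {"n": 180.0, "p2o5": 240.0, "k2o": 150.0}

#: the prescription equations as published (coefficients at 2 decimals).
#: Note the published rounding is not everywhere the 2-decimal rounding of
#: the coefficients derived from BASIC_PARAMETERS (a_p2o5 0.61 vs derived
#: 0.62; a_k2o 0.82 vs derived 0.81).
PUBLISHED_EQUATIONS = EquationSet(
    n=NutrientEquation(a=0.69, b=0.37, c=0.62, floor=60.0, cap=180.0),
    p2o5=NutrientEquation(a=0.61, b=0.54, c=0.86, cap=240.0),
    k2o=NutrientEquation(a=0.82, b=0.42, c=0.63, floor=50.0, cap=150.0),
)

#: manure composition used for the reference reckoner (26% moisture;
#: 0.56 / 0.23 / 0.47 per cent N / P / K on fresh weight)
FYM_SPEC = FymSpec(moisture_fraction=0.26, n_pct=0.56, p_pct=0.23, k_pct=0.47, basis="fresh")

#: manure credits at 12.5 t/ha back-computed from the published fertilizer
#: savings (37 / 26 / 34 kg of N / P2O5 / K2O) and the c coefficients;
#: they match neither the fresh- nor the dry-basis credit of FYM_SPEC
#: exactly, so the reference reckoner uses them explicitly.
RECKONER_FYM_CREDITS_12_5 = Credits(37.0 / 0.62, 26.0 / 0.86, 34.0 / 0.63)

#: reference reckoner layout: yield target and soil-test grids (element basis)
RECKONER_TARGET_Q = 400.0
RECKONER_STV_GRIDS = {
    "n": [400.0, 420.0, 440.0, 460.0, 480.0, 500.0],
    "p2o5": [180.0, 190.0, 200.0, 210.0, 220.0, 230.0],
    "k2o": [520.0, 540.0, 560.0, 580.0, 600.0, 620.0],
}

#: strip-wise pre-sowing soil-test means for the test crop, kg/ha element
#: basis (KMnO4-N, Bray-P, NH4OAc-K), strips I..III
STRIP_STV_MEANS = {
    "n": (416.0, 435.0, 475.0),
    "p2o5": (184.3, 197.4, 209.4),
    "k2o": (515.0, 552.0, 620.0),
}
#: strip-wise soil-test coefficients of variation (%), from the descriptive
#: statistics of the gradient field
STRIP_STV_CVS_PCT = {
    "n": (2.70, 2.01, 2.37),
    "p2o5": (2.77, 2.20, 2.16),
    "k2o": (2.56, 0.76, 1.45),
}

#: general fertilizer recommended dose and farmer's practice (kg/ha N, P2O5, K2O)
GFRD_DOSES = (120.0, 160.0, 100.0)
FFP_DOSES = (100.0, 120.0, 80.0)

#: mean harvested yields (t/ha) of the non-targeted validation treatments
BASELINE_YIELDS_T_HA = {
    "gfrd": 28.45,
    "gfrd_fym": 29.46,
    "ffp": 26.42,
    "absolute_control": 24.96,
}

#: strip-mean summary of the test-crop phase: inorganic-treated vs control
#: plot means (kg/ha), used for desk-scale cross-checks of the estimators
TREATED_MEANS = {"yield": 41951.0, "u_n": 156.08, "u_p": 52.45, "u_k": 155.43,
                 "s_n": 442.33, "s_p": 197.0, "s_k": 562.0}
CONTROL_MEANS = {"yield": 19099.0, "u_n": 97.4, "u_p": 23.1, "u_k": 120.54,
                 "s_n": 438.89, "s_p": 196.3, "s_k": 566.0}


def validation_trial() -> pd.DataFrame:
    """The reference validation trial: treatments, doses and harvested yields.

    Ten treatments in the published layout: the general recommended dose with
    and without manure, targeted-yield inorganic and integrated prescriptions
    at 35/40/45 t/ha, farmer's practice, and an absolute control.
    """
    rows = [
        ("gfrd", 0.0, 120.0, 160.0, 100.0, 28.45, None),
        ("gfrd_fym", 12.5, 120.0, 160.0, 100.0, 29.46, None),
        ("stcr_npk_35t", 0.0, 123.0, 141.0, 89.0, 35.45, 35.0),
        ("stcr_npk_40t", 0.0, 172.0, 201.0, 128.0, 39.40, 40.0),
        ("stcr_npk_45t", 0.0, 180.0, 240.0, 150.0, 43.42, 45.0),
        ("stcr_ipns_35t", 12.5, 91.0, 114.0, 50.0, 36.22, 35.0),
        ("stcr_ipns_40t", 12.5, 140.0, 174.0, 77.0, 40.36, 40.0),
        ("stcr_ipns_45t", 12.5, 180.0, 233.0, 116.0, 43.60, 45.0),
        ("ffp", 0.0, 100.0, 120.0, 80.0, 26.42, None),
        ("absolute_control", 0.0, 0.0, 0.0, 0.0, 24.96, None),
    ]
    return pd.DataFrame(rows, columns=list(VALIDATION_COLUMNS))
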