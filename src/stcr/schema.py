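"""Column schemas shared by the trial generator, estimators and file I/O.

Plot tables are plain pandas DataFrames with one row per experimental plot.
Doses are on the oxide basis for P and K (P2O5, K2O) while soil-test values
and uptakes are on the element basis (Bray-P, NH4OAc-K are reported as P and
K), mirroring how soil-testing laboratories and fertilizer schedules report
these quantities.
"""

from __future__ import annotations

NUTRIENTS = ("n", "p2o5", "k2o")

#: plot-table column order (one row per plot)
PLOT_COLUMNS = (
    "plot_id",
    "strip",
    "fym_t_ha",
    "f_n",
    "f_p2o5",
    "f_k2o",
    "s_n",
    "s_p",
    "s_k",
    "yield_kg_ha",
    "u_n",
    "u_p",
    "u_k",
)

#: validation-trial column order (one row per treatment)
VALIDATION_COLUMNS = (
    "treatment",
    "fym_t_ha",
    "f_n",
    "f_p2o5",
    "f_k2o",
    "yield_t_ha",
    "target_t_ha",
)

#: nutrient -> fertilizer-dose column (oxide basis)
DOSE_COLUMN = {"n": "f_n", "p2o5": "f_p2o5", "k2o": "f_k2o"}
#: nutrient -> pre-sowing soil-test column (element basis)
STV_COLUMN = {"n": "s_n", "p2o5": "s_p", "k2o": "s_k"}
#: nutrient -> total-uptake column (element basis)
UPTAKE_COLUMN = {"n": "u_n", "p2o5": "u_p", "k2o": "u_k"}

#: predictors of the corroborating multiple-regression yield model
YIELD_MODEL_PREDICTORS = (
    "u_n",
    "u_p",
    "u_k",
    "s_n",
    "s_p",
    "s_k",
    "f_n",
    "f_p2o5",
    "f_k2o",
    "fym_t_ha",
)
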