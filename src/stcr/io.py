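"""Reading and writing the plot and validation CSV tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .schema import PLOT_COLUMNS, VALIDATION_COLUMNS

DOSE_COLUMNS = ("f_n", "f_p2o5", "f_k2o", "fym_t_ha")


class TableFormatError(ValueError):
    pass


def _read_table(path: str | Path, columns: tuple[str, ...], id_column: str) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    for col in columns:
        if col not in df.columns:
            raise TableFormatError(f"missing column: {col}")
    numeric = [c for c in columns if c != id_column]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise TableFormatError(f"non-numeric cell at line {row}, column {col!r}")
        df[col] = coerced
    for col in DOSE_COLUMNS:
        if col in df.columns and (df[col] < 0).any():
            row = int((df[col] < 0).idxmax()) + 2
            raise TableFormatError(f"negative dose at line {row}, column {col!r}")
    return df[list(columns)]


def read_plot_table(path: str | Path) -> pd.DataFrame:
    """Read a plot table, validating schema, numeric cells and dose signs."""
    return _read_table(path, PLOT_COLUMNS, id_column="plot_id")


def write_plot_table(plots: pd.DataFrame, path: str | Path) -> None:
    plots[list(PLOT_COLUMNS)].to_csv(path, index=False)


def read_validation_table(path: str | Path) -> pd.DataFrame:
    """Read a validation-trial table (treatment labels plus numeric fields).

    ``target_t_ha`` may be blank for treatments without a yield target.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in VALIDATION_COLUMNS:
        if col not in df.columns:
            raise TableFormatError(f"missing column: {col}")
    numeric = [c for c in VALIDATION_COLUMNS if c != "treatment"]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if col != "target_t_ha":
            bad |= df[col].isna()
        if bad.any():
            row = int(bad.idxmax()) + 2
            raise TableFormatError(f"non-numeric cell at line {row}, column {col!r}")
        df[col] = coerced
    return df[list(VALIDATION_COLUMNS)]


def write_validation_table(records: pd.DataFrame, path: str | Path) -> None:
    records[list(VALIDATION_COLUMNS)].to_csv(path, index=False)
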