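"""Reading and writing long-format plot tables and report files."""

from __future__ import annotations

import pandas as pd

__all__ = ["REQUIRED_COLUMNS", "read_long_csv", "write_long_csv", "validate_long_table"]

REQUIRED_COLUMNS = ("genotype", "season", "regime", "rep", "trait", "value")
KEY_COLUMNS = ("genotype", "season", "regime", "rep", "trait")


def validate_long_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format plot table: required columns, numeric values,
    no duplicate plot keys. Errors carry the offending row number (0-based,
    excluding the header)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    values = pd.to_numeric(table["value"], errors="coerce")
    bad = table.index[values.isna() & table["value"].notna()]
    if len(bad):
        raise ValueError(
            f"non-numeric value at row {bad[0]}: {table.loc[bad[0], 'value']!r}"
        )
    if values.isna().any():
        raise ValueError(f"missing value at row {values.index[values.isna()][0]}")
    out = table.copy()
    out["value"] = values.astype(float)
    out["rep"] = pd.to_numeric(out["rep"]).astype(int)
    dup = out.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        row = out.index[dup][0]
        key = tuple(out.loc[row, list(KEY_COLUMNS)])
        raise ValueError(f"duplicate plot key {key} at row {row}")
    return out[list(REQUIRED_COLUMNS) + [c for c in out.columns if c not in REQUIRED_COLUMNS]]


def read_long_csv(path) -> pd.DataFrame:
    """Read and validate a long-format plot CSV."""
    return validate_long_table(pd.read_csv(path))


def write_long_csv(table: pd.DataFrame, path) -> None:
    table[list(REQUIRED_COLUMNS)].to_csv(path, index=False)
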