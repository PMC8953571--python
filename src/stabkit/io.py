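"""Schema-validated CSV input for the analysis stages.

All inputs are plain UTF-8 CSV with ``.`` decimals and exact header
names. Errors name the offending row and column; unknown extra columns
are tolerated with a warning so instrument exports with bookkeeping
columns load unchanged.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

__all__ = ["SchemaError", "SCHEMAS", "load_table"]


class SchemaError(ValueError):
    """A CSV that does not match its documented schema."""


#: schema id -> (required columns -> dtype, optional columns -> dtype)
SCHEMAS: dict[str, tuple[dict[str, str], dict[str, str]]] = {
    "time_course": (
        {"condition": "str", "time_h": "float", "conc_ug_ml": "float"},
        {},
    ),
    "calibration": (
        {"conc_ug_ml": "float", "replicate": "int", "area": "float"},
        {},
    ),
    "trace": ({"time_min": "float", "signal": "float"}, {}),
    "peaks": ({"compound": "str", "mz": "float"}, {"intensity": "float"}),
    "candidates": (
        {"compound": "str", "formula": "str"},
        {"calc_mz": "float"},
    ),
    "stress": (
        {
            "condition": "str",
            "duration_h": "float",
            "area_unstressed": "float",
            "area_stressed": "float",
        },
        {},
    ),
    "recovery": (
        {"level": "str", "series": "str", "found_ug_ml": "float"},
        {},
    ),
}


def load_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Load and validate a CSV against a named schema.

    Returns a typed DataFrame whose index preserves the file row number
    (header = row 1, first data row = row 2) for error reporting.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; have {sorted(SCHEMAS)}")
    required, optional = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required and c not in optional]
    if extra:
        warnings.warn(f"{path}: ignoring unrecognized column(s) {extra}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    df.index = df.index + 2  # file row numbers
    out = pd.DataFrame(index=df.index)
    for col, dtype in {**required, **{c: t for c, t in optional.items() if c in df.columns}}.items():
        raw = df[col]
        if dtype == "str":
            out[col] = raw.astype(str)
            continue
        converted = pd.to_numeric(raw.replace("", pd.NA), errors="coerce")
        bad = converted.isna() & (raw != "")
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"{path}: non-numeric value {raw.loc[row]!r} in column "
                f"{col!r} at row {row}"
            )
        if converted.isna().any():
            row = int(converted.isna().idxmax())
            raise SchemaError(f"{path}: empty cell in column {col!r} at row {row}")
        out[col] = converted.astype(float if dtype == "float" else int)
    return out
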