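"""Tabular and parameter I/O.

Tabular data travel as UTF-8 tab-separated files with a header row of
unit-suffixed column names (t_s, X_nm, F_pN, U_mV, I_uA, ...); numeric
round trips are lossless at 17 significant digits.  Parameters and results
travel as flat JSON with unit-suffixed keys.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "read_timeseries",
    "write_timeseries",
    "read_params",
    "write_params",
]


class SchemaError(ValueError):
    """A required column is missing or a value failed to parse."""


def write_timeseries(path, df: pd.DataFrame) -> None:
    """Write a table as TSV with 17-significant-digit floats."""
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_timeseries(path, required: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a TSV table, checking for required columns.

    Parsing is locale-independent: only '.' decimal separators are valid,
    and any non-numeric cell (for example a comma decimal) raises
    SchemaError.
    """
    df = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    if required:
        missing = sorted(set(required) - set(df.columns))
        if missing:
            raise SchemaError(f"{path}: missing required columns {missing}")
    string_cols = {"cell_id", "state", "branch", "model", "regime"}
    check = [c for c in (required or df.columns) if c not in string_cols]
    for col in check:
        if df[col].dtype == object:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as err:
                raise SchemaError(f"{path}: column {col!r} is not numeric: {err}") from err
    return df


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v


def write_params(path, params: dict) -> None:
    """Write a flat parameter/result dict as pretty JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({k: _jsonable(v) for k, v in params.items()}, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_params(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
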