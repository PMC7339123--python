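"""CSV schemas and guarded table I/O.

All assay tables move through headered CSV with fixed column sets; a
header mismatch raises :class:`SchemaError` naming the missing columns
instead of silently mis-assigning data, and comma decimal marks (a
frequent instrument-export dialect) are rejected explicitly rather
than parsed as strings.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import SchemaError

#: required columns per schema; extra columns are preserved
SCHEMAS: dict[str, list[str]] = {
    "trace": ["time_s", "current_pA"],
    "thermogram": ["temp_C", "cp_excess"],
    "leakage": ["time_min", "fluorescence"],
    "adsorption": ["conc_uM", "dphi_mV"],
    "adsorption_conductance": ["conc_uM", "g_m_nS", "g_m0_nS"],
    "ratio": ["conc_uM", "R"],
    "descriptors": ["compound"],
    "effects": ["compound"],
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a schema-validated CSV table."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise SchemaError(f"{path}: empty or missing table")
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise SchemaError(f"{path}: table has no rows")
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing} for schema {schema!r}")
    for col in SCHEMAS[schema]:
        if col == "compound":
            continue
        if df[col].dtype == object:
            sample = df[col].astype(str).head(20).str.contains(",").any()
            hint = " (comma decimal marks? use '.' as the decimal separator)" if sample else ""
            raise SchemaError(f"{path}: column {col!r} is not numeric{hint}")
    return df


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    """Write a CSV table after validating it against a schema."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write: missing required columns {missing} for schema {schema!r}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(obj):
    import numpy as np

    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return obj.__dict__
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json(path):
    return json.loads(Path(path).read_text())
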