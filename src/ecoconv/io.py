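"""Strict CSV readers/writers for observation tables.

Dialect: UTF-8, comma-separated, '.' decimal point, mandatory header.
Malformed rows are reported with their (1-based, header-exclusive) row
numbers rather than silently coerced.
"""

from __future__ import annotations

from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import OBSERVATION_COLUMNS

__all__ = ["read_observations", "write_table", "ObservationSchemaError"]


class ObservationSchemaError(ValueError):
    """Raised when an observation file does not conform to the schema."""


_NUMERIC = ("day", "time_h", "body_weight_g", "stomach_content_g", "temperature_C")


def read_observations(path) -> pd.DataFrame:
    """Read and validate a fish-observation table.

    Required columns: ``fish_id, condition, day, time_h, body_weight_g,
    stomach_content_g, temperature_C``.  Rows with non-numeric fields,
    non-positive body weight or negative stomach content are rejected with
    their row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ObservationSchemaError(
            f"{path}: missing columns {missing}; expected schema "
            f"{list(OBSERVATION_COLUMNS)}"
        )
    bad: list[tuple[int, str]] = []
    out = df.copy()
    for col in _NUMERIC:
        vals = pd.to_numeric(df[col].str.strip(), errors="coerce")
        for idx in df.index[vals.isna()]:
            bad.append((int(idx) + 1, f"non-numeric {col}={df.at[idx, col]!r}"))
        out[col] = vals
    if not bad:
        for idx in out.index[out["body_weight_g"] <= 0]:
            bad.append((int(idx) + 1, "body_weight_g must be positive"))
        for idx in out.index[out["stomach_content_g"] < 0]:
            bad.append((int(idx) + 1, "stomach_content_g must be non-negative"))
        for idx in out.index[out["time_h"] < 0]:
            bad.append((int(idx) + 1, "time_h must be non-negative"))
    if bad:
        detail = "; ".join(f"row {r}: {msg}" for r, msg in bad[:10])
        more = f" (+{len(bad) - 10} more)" if len(bad) > 10 else ""
        raise ObservationSchemaError(f"{path}: {detail}{more}")
    out["day"] = out["day"].astype(int)
    ids = pd.to_numeric(out["fish_id"], errors="coerce")
    if not ids.isna().any():  # ids may be arbitrary labels; keep ints as ints
        out["fish_id"] = ids.astype(int) if (ids % 1 == 0).all() else ids
    return out


def write_table(obj, path) -> Path:
    """Write a DataFrame or a list of dataclass records as strict CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, pd.DataFrame):
        df = obj
    elif is_dataclass(obj):
        df = pd.DataFrame([asdict(obj)])
    else:
        records = [asdict(r) if is_dataclass(r) else dict(r) for r in obj]
        df = pd.DataFrame.from_records(records)
    df = df.copy()
    for col in df.columns:  # residual arrays are not table cells
        if df[col].map(lambda v: isinstance(v, np.ndarray)).any():
            df = df.drop(columns=[col])
    df.to_csv(path, index=False)
    return path
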