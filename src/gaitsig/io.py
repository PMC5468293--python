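"""CSV readers/writers and JSON result serialization.

Schemas (comma-separated, mandatory header, UTF-8, '.' decimal; units baked
into column names):

* Stride CSV: ``subject_id, trial_id, paw, cue, stride_velocity_cm_s,
  stride_length_mm, stride_s, swing_s, stance_s, cadence_per_s,
  swing_speed_mm_s, base_width_mm`` (last column optional).
* Footfall CSV: ``subject_id, trial_id, paw, swing_onset_s, swing_offset_s,
  touchdown_mm, lateral_mm, cue`` (lateral optional).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import FOOTFALL_COLUMNS, STRIDE_COLUMNS, StrideTable

__all__ = [
    "read_stride_csv",
    "write_stride_csv",
    "read_footfall_csv",
    "write_results",
]

_STRIDE_NUMERIC = (
    "stride_velocity_cm_s",
    "stride_length_mm",
    "stride_s",
    "swing_s",
    "stance_s",
    "cadence_per_s",
    "swing_speed_mm_s",
    "base_width_mm",
)
_FOOTFALL_NUMERIC = ("swing_onset_s", "swing_offset_s", "touchdown_mm", "lateral_mm")


def _coerce_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            lines = [int(i) + 2 for i in df.index[bad][:10]]  # +2: header + 1-based
            raise ValueError(
                f"{path}: non-numeric values in column {col!r} at line(s) {lines}"
            )
        df[col] = coerced
    return df


def read_stride_csv(path, identity_rtol: float = 1e-6) -> StrideTable:
    """Read a stride CSV, validating schema and per-stride identities.

    Missing required columns raise naming the columns; non-numeric cells
    raise with their line numbers; identity violations beyond
    ``identity_rtol`` produce a warning listing the offending lines.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    required = [c for c in STRIDE_COLUMNS if c != "base_width_mm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    df = _coerce_numeric(df, _STRIDE_NUMERIC, path)
    if "base_width_mm" not in df.columns:
        df["base_width_mm"] = np.nan
    table = StrideTable(df[list(STRIDE_COLUMNS)], {"source": str(path)})
    bad = table.identity_violations(rtol=identity_rtol)
    if len(bad):
        lines = [int(i) + 2 for i in bad.index[:10]]
        warnings.warn(
            f"{path}: {len(bad)} stride(s) violate kinematic identities "
            f"beyond rtol={identity_rtol:g}; line(s) {lines}",
            stacklevel=2,
        )
    return table


def write_stride_csv(table: StrideTable, path) -> None:
    """Write a stride CSV; lossless round-trip with :func:`read_stride_csv`."""
    table.data.to_csv(path, index=False, columns=list(STRIDE_COLUMNS))


def read_footfall_csv(path) -> pd.DataFrame:
    """Read a footfall-event CSV into the documented event schema."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = [c for c in FOOTFALL_COLUMNS if c != "lateral_mm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    df = _coerce_numeric(df, _FOOTFALL_NUMERIC, path)
    if "lateral_mm" not in df.columns:
        df["lateral_mm"] = np.nan
    return df[list(FOOTFALL_COLUMNS)]


class _ResultEncoder(json.JSONEncoder):
    def default(self, o):
        if hasattr(o, "to_dict"):
            return o.to_dict()
        if is_dataclass(o) and not isinstance(o, type):
            return asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, tuple)):
            return list(o)
        return super().default(o)


def write_results(results, path) -> None:
    """Serialize analysis result objects (fits, comparisons, reports) to JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _keys(obj):
        if isinstance(obj, dict):
            return {
                (k if isinstance(k, (str, int, float, bool)) or k is None else "/".join(map(str, k))): _keys(v)
                for k, v in obj.items()
            }
        if isinstance(obj, (list, tuple)):
            return [_keys(v) for v in obj]
        return obj

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_keys(results), fh, cls=_ResultEncoder, indent=2, allow_nan=True)
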