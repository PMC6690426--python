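"""Table readers/writers for survival data and result objects.

Survival tables are delimited text (TSV/CSV, auto-detected) with one row
per patient and named columns for time, event and group.  Event codes other
than {0, 1}/{true, false} must be mapped explicitly — silent miscoding of
the event flag is the classic survival-analysis bug.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd

from .datasets import SurvivalDataset, validate_dataset

__all__ = ["read_survival_table", "read_solution_labels", "write_results",
           "to_jsonable"]


def _read_table(path, sep: Optional[str]) -> pd.DataFrame:
    if sep is None:
        return pd.read_csv(path, sep=None, engine="python")
    return pd.read_csv(path, sep=sep)


def read_survival_table(path,
                        time_col: str = "time",
                        event_col: str = "event",
                        group_col: str = "group",
                        sep: Optional[str] = None,
                        id_col: Optional[str] = None,
                        **validate_kwargs) -> SurvivalDataset:
    """Read a per-patient survival table and validate it.

    ``sep=None`` auto-detects tab vs comma.  When ``id_col`` is given the
    patient ids are attached (used to join clustering-solution files).
    """
    df = _read_table(path, sep)
    missing = [c for c in (time_col, event_col, group_col) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; "
                         f"found {list(df.columns)}")
    try:
        times = pd.to_numeric(df[time_col], errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        bad = pd.to_numeric(df[time_col], errors="coerce")
        row = int(bad.index[bad.isna()][0])
        raise ValueError(f"{path}: unparseable time value "
                         f"{df[time_col].iloc[row]!r} at row {row}") from exc
    data = validate_dataset(times, df[event_col].tolist(),
                            df[group_col].tolist(), **validate_kwargs)
    if id_col is not None:
        if id_col not in df.columns:
            raise ValueError(f"{path}: missing id column {id_col!r}")
        object.__setattr__(data, "_ids", tuple(df[id_col].astype(str)))
    return data


def read_solution_labels(path, ids: Optional[Sequence[str]] = None,
                         sep: Optional[str] = None) -> np.ndarray:
    """Read a two-column (patient id, cluster) solution file.

    With ``ids`` given, labels are joined on id; otherwise row order is
    assumed to match the survival table.
    """
    df = _read_table(path, sep)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: solution files need two columns "
                         "(patient id, cluster)")
    id_col, lab_col = df.columns[0], df.columns[1]
    if ids is None:
        return df[lab_col].to_numpy()
    table = dict(zip(df[id_col].astype(str), df[lab_col]))
    missing = [i for i in ids if str(i) not in table]
    if missing:
        raise ValueError(f"{path}: no cluster label for patient id(s) "
                         f"{missing[:5]}{'...' if len(missing) > 5 else ''}")
    return np.asarray([table[str(i)] for i in ids], dtype=object)


def to_jsonable(obj: Any) -> Any:
    """Recursively convert results (dataclasses, numpy) to JSON-safe types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return [to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    return obj


def write_results(result: Any, path, fmt: str = "json") -> None:
    """Write a result object as JSON or TSV.

    JSON output is byte-stable for identical inputs and seeds: keys keep
    dataclass field order and floats use shortest round-trip notation.
    """
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(to_jsonable(result), indent=2) + "\n")
    elif fmt == "tsv":
        rows = result if isinstance(result, (list, tuple)) else [result]
        frame = pd.DataFrame([to_jsonable(r) for r in rows])
        frame.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")
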