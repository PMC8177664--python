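"""Readers and writers for the long peak-table CSV and config files.

The canonical interchange format is a long CSV with one row per injection
per analyte (columns ``injection_index, sample_id, role, batch_id,
study_id, analyte, area, is_area`` plus optional nominal fields); wide PAR
matrices are derived in-memory views, never a storage format.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .tables import LONG_COLUMNS, PeakTable


def read_peak_table(path: str | Path) -> PeakTable:
    """Read and validate a long peak-table CSV.

    Raises a distinct error for missing columns, non-positive IS areas and
    duplicate (injection, analyte) pairs.
    """
    df = pd.read_csv(path)
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns: {sorted(missing)}")
    return PeakTable(df)


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True))


def write_truth_sidecar(truth: dict, path: str | Path) -> None:
    """Persist a simulation ground-truth record as JSON (config excluded
    fields that are not JSON-friendly are serialized by value)."""
    out = {}
    for k, v in truth.items():
        if k == "config":
            out[k] = {f.name: _jsonable(getattr(v, f.name))
                      for f in dataclasses.fields(v) if f.name != "panel"}
        elif k == "drift_curves":
            out[k] = {b: list(map(float, c)) for b, c in v.items()}
        else:
            out[k] = _jsonable(v)
    write_json(out, path)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
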