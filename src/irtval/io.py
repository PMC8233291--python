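"""Readers and writers for response matrices, item banks, and reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .banks import ItemBank, ResponseMatrix


def read_responses(path: str | Path, bank: ItemBank | None = None) -> ResponseMatrix:
    """Read a respondent-by-item CSV (header = item ids; optional ``group``
    and ``true_theta`` columns) with validation.

    Cells must be positive integers; when a bank is supplied, categories
    are range-checked against each item's K and the error names the cell.
    """
    rm = ResponseMatrix.from_csv(path)
    for col in rm.item_ids:
        vals = rm.data[col].dropna()
        bad = vals[(vals < 1) | (vals != np.round(vals))]
        if len(bad):
            raise ValueError(
                f"{path}: invalid category {bad.iloc[0]!r} for item {col!r} "
                f"(row {bad.index[0]}): categories are integers starting at 1"
            )
    if bank is not None:
        rm.validate_against_bank(bank)
    return rm


def write_responses(rm: ResponseMatrix, path: str | Path) -> None:
    rm.to_csv(path)


def read_bank(path: str | Path) -> ItemBank:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return ItemBank.from_frame(pd.read_csv(path))
    return ItemBank.from_json(path)


def write_bank(bank: ItemBank, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        bank.to_frame().to_csv(path, index=False)
    else:
        bank.to_json(path)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    if hasattr(obj, "__dict__") and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in vars(obj).items()}
    return obj


def write_report(report, out_dir: str | Path) -> Path:
    """Write a ValidationReport as ``report.json`` plus tidy per-section
    CSVs under ``out_dir``.  Returns the JSON path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    d = report.to_dict()
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(_jsonable(d), indent=2, sort_keys=True,
                                    allow_nan=False, default=str))
    for name, frame in report.tables().items():
        frame.to_csv(out_dir / f"{name}.csv", index=False)
    return json_path
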