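"""File formats: response matrices, item banks, triad sets, subset plans.

CSV is the lingua franca for tabular artifacts, JSON for structured
metadata.  All readers validate aggressively and name the offending
cell/column in error messages; all writers round-trip their reader at 12
significant digits for parameter values.

Dialects
--------
ResponseMatrix
    CSV, first column ``respondent_id``, header row of item ids, cells in
    {0, 1, NA} (empty cells also read as missing).
ItemBank
    CSV with columns ``item_id,beta,alpha,c`` (``alpha``/``c`` optional,
    defaulting to the Rasch convention 1 and 0 with a warning), or JSON
    carrying ``items`` plus ``calibration_meta``.
TriadSet / SubsetPlan / AbilityEstimates
    CSV roster resp. JSON plan as documented on the writers.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .irt import AbilityEstimates, ItemBank, ItemParameters, ResponseMatrix
from .subsets import SubsetPlan
from .triads import TriadSet

__all__ = [
    "read_response_matrix",
    "write_response_matrix",
    "read_item_bank",
    "write_item_bank",
    "write_abilities",
    "read_abilities",
    "write_triads",
    "write_subset_plans",
    "read_subset_plans",
]

_FLOAT_FMT = "%.12g"


def read_response_matrix(path) -> ResponseMatrix:
    """Read a respondents x items CSV of {0, 1, NA} cells."""
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, index_col=0, keep_default_na=False)
    parsed = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col]):
            cell = cell.strip()
            if cell in ("", "NA", "NaN", "nan"):
                parsed.iat[i, j] = np.nan
            elif cell in ("0", "1"):
                parsed.iat[i, j] = float(cell)
            else:
                raise ValueError(
                    f"{path.name}: cell must be 0, 1 or NA; found {cell!r} at "
                    f"respondent {raw.index[i]!r}, item {col!r}"
                )
    return ResponseMatrix(parsed)


def write_response_matrix(responses: ResponseMatrix, path) -> None:
    frame = responses.frame.copy()
    out = frame.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.index.name = "respondent_id"
    out.to_csv(path)


def _items_from_frame(frame: pd.DataFrame, source: str) -> list[ItemParameters]:
    for required in ("item_id", "beta"):
        if required not in frame.columns:
            raise ValueError(f"{source}: missing required column {required!r}")
    if "alpha" not in frame.columns:
        warnings.warn(
            f"{source}: no 'alpha' column, defaulting slopes to 1 (Rasch convention)",
            RuntimeWarning,
            stacklevel=3,
        )
        frame = frame.assign(alpha=1.0)
    if "c" not in frame.columns:
        warnings.warn(
            f"{source}: no 'c' column, defaulting guessing to 0 (Rasch convention)",
            RuntimeWarning,
            stacklevel=3,
        )
        frame = frame.assign(c=0.0)
    return [
        ItemParameters(
            item_id=str(row.item_id),
            beta=float(row.beta),
            alpha=float(row.alpha),
            c=float(row.c),
        )
        for row in frame.itertuples(index=False)
    ]


def read_item_bank(path) -> ItemBank:
    """Read an item bank from CSV (parameters only) or JSON (with metadata)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        frame = pd.DataFrame(payload["items"])
        items = _items_from_frame(frame, path.name)
        return ItemBank(items, calibration_meta=payload.get("calibration_meta", {}))
    frame = pd.read_csv(path)
    return ItemBank(_items_from_frame(frame, path.name))


def write_item_bank(bank: ItemBank, path) -> None:
    """Write a bank as CSV (``.csv``) or JSON with calibration metadata."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "items": [
                {
                    "item_id": it.item_id,
                    "beta": float(_FLOAT_FMT % it.beta),
                    "alpha": float(_FLOAT_FMT % it.alpha),
                    "c": float(_FLOAT_FMT % it.c),
                }
                for it in bank
            ],
            "calibration_meta": bank.calibration_meta,
        }
        path.write_text(json.dumps(payload, indent=2))
        return
    frame = bank.to_frame()
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_abilities(abilities: AbilityEstimates, path) -> None:
    abilities.frame.to_csv(path, float_format=_FLOAT_FMT)


def read_abilities(path) -> AbilityEstimates:
    frame = pd.read_csv(path, index_col=0)
    return AbilityEstimates(frame)


def write_triads(triads: TriadSet, path) -> None:
    triads.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_subset_plans(plans: list[SubsetPlan], path) -> None:
    payload = [
        {"name": p.name, "item_ids": list(p.item_ids), "recipe": p.recipe}
        for p in plans
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_subset_plans(path) -> list[SubsetPlan]:
    payload = json.loads(Path(path).read_text())
    return [
        SubsetPlan(name=p["name"], item_ids=list(p["item_ids"]),
                   recipe=p.get("recipe", {}))
        for p in payload
    ]
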