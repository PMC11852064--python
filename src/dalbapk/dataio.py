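"""CSV dataset dialect: reading and writing event tables.

Columns: ID, TIME (h), EVID (1 dose / 0 observation), AMT (mg), DUR (h),
DV (mg/L), WT (kg), plus optional covariates CLCR, AGE, SEX, ALB, CRP,
HT.  Missing numeric fields are written as ".".  Doses carry AMT/DUR and
no DV; observations carry DV and no AMT/DUR.  Canonical files round-trip
byte-identically through read/write.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import COVARIATE_COLUMNS, REQUIRED_COLUMNS, StudyDataset

__all__ = ["read_dataset", "write_dataset", "DialectError"]

MISSING = "."


class DialectError(ValueError):
    """A dataset file violates the event-table dialect (message carries the line)."""


def _parse_float(token: str, line_no: int, column: str) -> float:
    if token == MISSING or token == "":
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise DialectError(
            f"line {line_no}: column {column} has non-numeric value {token!r}"
        ) from None


def read_dataset(path: str | Path) -> StudyDataset:
    """Read and validate a study dataset CSV; errors carry line numbers."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DialectError("empty file") from None
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise DialectError(f"header is missing required columns: {missing}")
        rows = []
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise DialectError(
                    f"line {line_no}: expected {len(header)} fields, got {len(row)}"
                )
            rec = dict(zip(header, row))
            parsed = {}
            for col in header:
                if col == "ID":
                    parsed[col] = rec[col]
                else:
                    parsed[col] = _parse_float(rec[col], line_no, col)
            evid = parsed["EVID"]
            if evid not in (0.0, 1.0):
                raise DialectError(f"line {line_no}: EVID must be 0 or 1, got {rec['EVID']!r}")
            parsed["EVID"] = int(evid)
            if parsed["EVID"] == 1 and not np.isnan(parsed["DV"]):
                raise DialectError(f"line {line_no}: dose row must not carry a DV value")
            if parsed["EVID"] == 0 and np.isnan(parsed["DV"]):
                raise DialectError(f"line {line_no}: observation row must carry a DV value")
            if parsed["TIME"] < 0:
                raise DialectError(f"line {line_no}: negative TIME")
            rows.append(parsed)
    if not rows:
        raise DialectError("file contains no event rows")
    df = pd.DataFrame(rows)
    try:
        return StudyDataset(df)
    except ValueError as exc:
        raise DialectError(str(exc)) from exc


def _format_value(value, column: str) -> str:
    if column == "ID":
        return str(value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return MISSING
    if column == "EVID":
        return str(int(value))
    return format(float(value), ".10g")


def write_dataset(dataset: StudyDataset, path: str | Path) -> None:
    """Write the canonical CSV form of a dataset."""
    df = dataset.events
    columns = list(REQUIRED_COLUMNS) + [
        c for c in COVARIATE_COLUMNS if c in df.columns
    ]
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for _, row in df.iterrows():
            writer.writerow([_format_value(row[c], c) for c in columns])
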