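"""Tidy CSV feature tables and JSON report serialization.

The on-disk table format is one row per animal per timepoint with header
``animal_id,class,timepoint_weeks,<feature names...>``; a missing value is
an empty field.  The class column accepts ``WT`` and ``DB`` (with
``Db/Db``-style aliases normalized to ``DB``).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .simulate import CLASS_DB, CLASS_WT, FeatureTable

_CLASS_ALIASES = {
    "wt": CLASS_WT,
    "db": CLASS_DB,
    "db/db": CLASS_DB,
    "dbdb": CLASS_DB,
}

_META_COLUMNS = ("animal_id", "class", "timepoint_weeks")


class ParseError(ValueError):
    pass


def normalize_class(token: str, line: int | None = None) -> str:
    norm = _CLASS_ALIASES.get(token.strip().lower())
    if norm is None:
        where = f" (line {line})" if line is not None else ""
        raise ParseError(f"unknown class token {token!r}{where}")
    return norm


def read_feature_csv(path) -> FeatureTable:
    """Read one timepoint's feature table from tidy CSV.

    Raises :class:`ParseError` (with line numbers) on unknown class tokens,
    duplicate animal ids, ragged rows, non-numeric cells, or multiple
    timepoints in one file.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if tuple(header[:3]) != _META_COLUMNS:
            raise ParseError(
                f"{path}: header must start with {','.join(_META_COLUMNS)}, got {header[:3]}"
            )
        feature_names = header[3:]
        if len(set(feature_names)) != len(feature_names):
            raise ParseError(f"{path}: duplicate feature columns")
        ids, labels, weeks, rows, masks = [], [], [], [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            animal, cls, week = row[0], normalize_class(row[1], lineno), row[2]
            try:
                weeks.append(int(week))
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: bad timepoint {week!r}") from None
            vals, miss = [], []
            for col, cell in zip(feature_names, row[3:]):
                if cell.strip() == "":
                    vals.append(np.nan)
                    miss.append(True)
                else:
                    try:
                        vals.append(float(cell))
                    except ValueError:
                        raise ParseError(
                            f"{path}: line {lineno}: non-numeric value {cell!r} in column {col!r}"
                        ) from None
                    miss.append(False)
            ids.append(animal)
            labels.append(cls)
            rows.append(vals)
            masks.append(miss)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    if len(set(weeks)) != 1:
        raise ParseError(f"{path}: multiple timepoints in one file: {sorted(set(weeks))}")
    if len(set(ids)) != len(ids):
        dupes = sorted({a for a in ids if ids.count(a) > 1})
        raise ParseError(f"{path}: duplicate animal ids within timepoint: {dupes}")
    return FeatureTable(
        animal_ids=ids,
        class_labels=np.array(labels, dtype=object),
        timepoint_weeks=weeks[0],
        feature_names=feature_names,
        values=np.array(rows, dtype=float),
        missing_mask=np.array(masks, dtype=bool),
    )


def write_feature_csv(table: FeatureTable, path) -> None:
    """Write a feature table as tidy CSV (missing cells become empty fields)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_META_COLUMNS) + table.feature_names)
        for i, animal in enumerate(table.animal_ids):
            row = [animal, str(table.class_labels[i]), str(table.timepoint_weeks)]
            for j in range(table.n_features):
                row.append("" if table.missing_mask[i, j] else repr(float(table.values[i, j])))
            writer.writerow(row)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
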