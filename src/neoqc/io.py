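"""Cohort CSV input/output.

One row per infant, RFC-4180 dialect, ISO-8601 dates, gestational age as
``weeks+days``.  A missing answer is an empty field; a structurally-missing
(inapplicable) value is the literal ``NA`` so the two survive a round trip.
Binary values are ``1``/``0``.

Malformed rows are collected into an error list, never raised, so a single
bad date costs one record rather than the run.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .records import (
    NOT_APPLICABLE,
    DataDictionary,
    GestationalAge,
    InfantRecord,
    default_dictionary,
)

_FIXED_COLUMNS = [
    "record_id",
    "unit_id",
    "birth_date",
    "gestational_age",
    "birth_weight",
    "sex",
    "multiple_birth",
    "delivery_room_death",
]

_NA_TOKEN = "NA"


@dataclass(frozen=True)
class RowError:
    line: int
    field: str
    message: str


def _encode(value, continuous: bool) -> str:
    if value is None:
        return ""
    if value is NOT_APPLICABLE:
        return _NA_TOKEN
    if continuous:
        return repr(float(value))
    return "1" if value else "0"


def _decode(text: str, continuous: bool):
    if text == "":
        return None
    if text == _NA_TOKEN:
        return NOT_APPLICABLE
    if continuous:
        return float(text)
    if text not in ("0", "1"):
        raise ValueError(f"binary value must be 0/1/NA/empty, got {text!r}")
    return text == "1"


def write_cohort(
    records: Iterable[InfantRecord],
    path: str | Path,
    dictionary: DataDictionary | None = None,
) -> None:
    dictionary = dictionary or default_dictionary()
    names = dictionary.names
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_FIXED_COLUMNS + names)
        for r in records:
            row = [
                r.record_id,
                r.unit_id,
                r.birth_date.isoformat(),
                "" if r.gestational_age is None else str(r.gestational_age),
                "" if r.birth_weight is None else f"{r.birth_weight:g}",
                "" if r.sex is None else r.sex,
                _encode(r.multiple_birth, False),
                "1" if r.delivery_room_death else "0",
            ]
            for name in names:
                row.append(_encode(r.items.get(name), dictionary[name].continuous))
            w.writerow(row)


def read_cohort(
    path: str | Path,
    dictionary: DataDictionary | None = None,
) -> tuple[list[InfantRecord], list[RowError]]:
    """Load a cohort CSV; malformed rows go to the error list.

    Item columns not present in the dictionary are rejected up front
    (schema mismatch); an empty file with a header only yields an empty
    cohort plus a warning entry.
    """
    dictionary = dictionary or default_dictionary()
    records: list[InfantRecord] = []
    errors: list[RowError] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return [], [RowError(0, "", "empty file: no header")]
        for col in _FIXED_COLUMNS:
            if col not in header:
                raise ValueError(f"schema mismatch: required column {col!r} missing")
        item_cols = [c for c in header if c not in _FIXED_COLUMNS]
        unknown = [c for c in item_cols if c not in dictionary]
        if unknown:
            raise ValueError(f"schema mismatch: unknown item columns {unknown}")
        idx = {c: header.index(c) for c in header}
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                records.append(_parse_row(row, idx, item_cols, dictionary))
            except Exception as exc:  # collect, don't crash
                errors.append(RowError(line_no, "", str(exc)))
    if not records and not errors:
        errors.append(RowError(1, "", "warning: header only, empty cohort"))
    return records, errors


def _parse_row(row, idx, item_cols, dictionary) -> InfantRecord:
    def get(col: str) -> str:
        return row[idx[col]]

    birth_date = dt.date.fromisoformat(get("birth_date"))
    ga_text = get("gestational_age")
    ga = GestationalAge.parse(ga_text) if ga_text else None
    bw_text = get("birth_weight")
    sex = get("sex") or None
    if sex not in (None, "male", "female"):
        raise ValueError(f"sex must be male/female/empty, got {sex!r}")
    items = {}
    for name in item_cols:
        items[name] = _decode(get(name), dictionary[name].continuous)
    return InfantRecord(
        record_id=get("record_id"),
        unit_id=get("unit_id"),
        birth_date=birth_date,
        gestational_age=ga,
        birth_weight=float(bw_text) if bw_text else None,
        sex=sex,
        multiple_birth=_decode(get("multiple_birth"), False),
        delivery_room_death=get("delivery_room_death") == "1",
        items=items,
    )
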