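"""Readers and writers for the diary CSV/JSON formats and results files.

Diary CSV header::

    event_id,start_time,end_time,pain_nrs,pulsating,pressing,one_sided,
    both_sided,aggravated_by_activity,aura,nausea,vomiting,photophobia,
    phonophobia,medication_taken,triptan_taken_and_effective

Timestamps are ISO 8601; booleans are encoded "1"/"0" on write and accepted
as 1/0, true/false, yes/no (case-insensitive) on read; an empty
``triptan_taken_and_effective`` cell means unknown.  The JSON diary is an
array of objects with the same field names.  Validation is total: any
malformed field is rejected with its row number and field name, never
silently coerced.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional, Sequence

import pandas as pd
from pydantic import ValidationError

from .engine import ClassificationResult
from .events import Certainty, HeadacheEvent, HeadacheLabel

DIARY_COLUMNS = [
    "event_id",
    "start_time",
    "end_time",
    "pain_nrs",
    "pulsating",
    "pressing",
    "one_sided",
    "both_sided",
    "aggravated_by_activity",
    "aura",
    "nausea",
    "vomiting",
    "photophobia",
    "phonophobia",
    "medication_taken",
    "triptan_taken_and_effective",
]

RESULT_COLUMNS = [
    "event_id",
    "label",
    "certainty",
    "short_duration_flag",
    "triptan_based",
    "probable_based",
    "rationale",
]

_BOOL_FLAGS = DIARY_COLUMNS[4:15]  # required yes/no columns

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}

Format = Literal["csv", "json"]


class DiaryValidationError(ValueError):
    """A diary or results record failed validation; names the row and field."""

    def __init__(self, row: int, field: str, message: str):
        self.row = row
        self.field = field
        super().__init__(f"row {row}, field {field!r}: {message}")


def _parse_bool(value: object, row: int, field: str) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise DiaryValidationError(row, field, f"not a boolean: {value!r}")


def _infer_format(path: str | Path, format: Optional[Format]) -> Format:
    if format is not None:
        return format
    suffix = Path(path).suffix.lower()
    if suffix == ".json":
        return "json"
    return "csv"


def _event_from_record(record: dict, row: int) -> HeadacheEvent:
    data: dict = {}
    for field in ("event_id", "start_time", "end_time"):
        if field not in record or record[field] in (None, ""):
            raise DiaryValidationError(row, field, "missing value")
        data[field] = record[field]
    try:
        data["pain_nrs"] = int(str(record.get("pain_nrs", "")).strip())
    except (TypeError, ValueError):
        raise DiaryValidationError(
            row, "pain_nrs", f"not an integer: {record.get('pain_nrs')!r}"
        ) from None
    for field in _BOOL_FLAGS:
        if field not in record or record[field] in (None, ""):
            raise DiaryValidationError(row, field, "missing value")
        data[field] = _parse_bool(record[field], row, field)
    triptan = record.get("triptan_taken_and_effective")
    if triptan in (None, ""):
        data["triptan_taken_and_effective"] = None
    else:
        data["triptan_taken_and_effective"] = _parse_bool(
            triptan, row, "triptan_taken_and_effective"
        )
    try:
        return HeadacheEvent(**data)
    except ValidationError as err:
        first = err.errors()[0]
        loc = first["loc"][0] if first["loc"] else "?"
        raise DiaryValidationError(row, str(loc), first["msg"]) from None
    except ValueError as err:  # cross-field invariant
        raise DiaryValidationError(row, "event", str(err)) from None


def read_diary(path: str | Path, format: Optional[Format] = None) -> list[HeadacheEvent]:
    """Read a diary file into validated events, preserving record order."""
    fmt = _infer_format(path, format)
    if fmt == "json":
        with open(path) as fh:
            records = json.load(fh)
        if not isinstance(records, list):
            raise DiaryValidationError(0, "document", "JSON diary must be an array")
    else:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in DIARY_COLUMNS[:-1] if c not in frame.columns]
        if missing:
            raise DiaryValidationError(0, missing[0], "missing column in header")
        records = frame.to_dict(orient="records")
    return [_event_from_record(rec, row) for row, rec in enumerate(records, start=1)]


def _event_to_record(event: HeadacheEvent, as_strings: bool) -> dict:
    rec: dict = {
        "event_id": event.event_id,
        "start_time": event.start_time.isoformat(),
        "end_time": event.end_time.isoformat(),
        "pain_nrs": event.pain_nrs,
    }
    for field in _BOOL_FLAGS:
        value = getattr(event, field)
        rec[field] = ("1" if value else "0") if as_strings else value
    triptan = event.triptan_taken_and_effective
    if triptan is None:
        rec["triptan_taken_and_effective"] = "" if as_strings else None
    else:
        rec["triptan_taken_and_effective"] = (
            ("1" if triptan else "0") if as_strings else triptan
        )
    return rec


def write_diary(
    events: Sequence[HeadacheEvent], path: str | Path, format: Optional[Format] = None
) -> None:
    """Write events to a diary file (inverse of :func:`read_diary`)."""
    fmt = _infer_format(path, format)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump([_event_to_record(e, as_strings=False) for e in events], fh, indent=1)
    else:
        frame = pd.DataFrame(
            [_event_to_record(e, as_strings=True) for e in events], columns=DIARY_COLUMNS
        )
        frame.to_csv(path, index=False)


def write_results(
    results: Sequence[ClassificationResult],
    path: str | Path,
    format: Optional[Format] = None,
) -> None:
    """Write classification results (labels, certainty, provenance flags)."""
    fmt = _infer_format(path, format)
    records = []
    for r in results:
        rec: dict = {
            "event_id": r.event_id,
            "label": r.label.value,
            "certainty": r.certainty.value,
            "rationale": r.rationale,
        }
        for field in ("short_duration_flag", "triptan_based", "probable_based"):
            value = getattr(r, field)
            rec[field] = ("1" if value else "0") if fmt == "csv" else value
        records.append(rec)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
    else:
        pd.DataFrame(records, columns=RESULT_COLUMNS).to_csv(path, index=False)


def read_results(
    path: str | Path, format: Optional[Format] = None
) -> list[ClassificationResult]:
    """Read a results file back (criteria traces are not serialized)."""
    fmt = _infer_format(path, format)
    if fmt == "json":
        with open(path) as fh:
            records = json.load(fh)
    else:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        records = frame.to_dict(orient="records")
    out = []
    for row, rec in enumerate(records, start=1):
        try:
            out.append(
                ClassificationResult(
                    event_id=str(rec["event_id"]),
                    label=HeadacheLabel(rec["label"]),
                    certainty=Certainty(rec["certainty"]),
                    short_duration_flag=_parse_bool(
                        rec["short_duration_flag"], row, "short_duration_flag"
                    ),
                    triptan_based=_parse_bool(rec["triptan_based"], row, "triptan_based"),
                    probable_based=_parse_bool(
                        rec["probable_based"], row, "probable_based"
                    ),
                    rationale=str(rec.get("rationale", "")),
                )
            )
        except (KeyError, ValueError) as err:
            if isinstance(err, DiaryValidationError):
                raise
            raise DiaryValidationError(row, "record", str(err)) from None
    return out


def read_labels(path: str | Path, format: Optional[Format] = None) -> list[HeadacheLabel]:
    """Read the label column from a results file or a truth file.

    Accepts any CSV/JSON with a ``label`` (or ``true_label``) field.
    """
    fmt = _infer_format(path, format)
    if fmt == "json":
        with open(path) as fh:
            records = json.load(fh)
    else:
        records = pd.read_csv(path, dtype=str, keep_default_na=False).to_dict(
            orient="records"
        )
    labels = []
    for row, rec in enumerate(records, start=1):
        raw = rec.get("label", rec.get("true_label"))
        if raw is None:
            raise DiaryValidationError(row, "label", "no label/true_label field")
        try:
            labels.append(HeadacheLabel(raw))
        except ValueError:
            raise DiaryValidationError(row, "label", f"unknown label {raw!r}") from None
    return labels


def events_to_frame(events: Sequence[HeadacheEvent]) -> pd.DataFrame:
    """Represent events as a DataFrame with the diary columns."""
    return pd.DataFrame(
        [_event_to_record(e, as_strings=False) for e in events], columns=DIARY_COLUMNS
    )


def frame_to_events(frame: pd.DataFrame) -> list[HeadacheEvent]:
    """Validate a diary-column DataFrame into events."""
    return [
        _event_from_record(rec, row)
        for row, rec in enumerate(frame.to_dict(orient="records"), start=1)
    ]
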