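"""Readers and writers for note tables, annotations and extraction results.

The primary interchange format is delimiter-separated text (CSV/TSV
inferred from the file extension); spreadsheet ingestion (.xlsx) is an
optional adapter.  Note DateTimes are read in one of two flagged
dialects: ``iso`` (``YYYY-MM-DD HH:MM``) or ``canonical``
(``MM/DD/YYYY HH:MM``).  Extraction results are serialized as one JSON
object per note, with no run metadata inside the payload so identical
inputs produce identical output files.
"""

from __future__ import annotations

import json
import logging
from datetime import datetime
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import hybrid, regexsuite
from .hybrid import ExtractionResult
from .types import (
    ClinicalNote,
    ExpressionKind,
    FormatCategory,
    Meridiem,
    NormalizedOnset,
    NoteType,
    OffsetUnit,
    OnsetAnnotation,
    Stage,
    TimeExpression,
    format_datetime,
    parse_datetime,
)

logger = logging.getLogger(__name__)

NOTE_COLUMNS = ("note_id", "note_type", "note_datetime", "text")
ANNOTATION_COLUMNS = ("note_id", "onset_datetime")

_NOTE_TYPE_ALIASES = {
    "HP": NoteType.HP,
    "H&P": NoteType.HP,
    "HISTORY AND PHYSICAL": NoteType.HP,
    "TRIAGE": NoteType.TRIAGE,
    "TRIAGE NOTES": NoteType.TRIAGE,
    "ED_SCREEN": NoteType.ED_SCREEN,
    "ED SCREENING": NoteType.ED_SCREEN,
    "ED SCREENING - FIRST CONTACT": NoteType.ED_SCREEN,
}


class SchemaError(ValueError):
    """The input table is missing a required column."""


class RowError(ValueError):
    """A row failed to parse; carries the 0-based row number."""

    def __init__(self, message: str, row: int):
        super().__init__(f"row {row}: {message}")
        self.row = row


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".tsv":
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path, dtype=str).fillna("")
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def parse_note_datetime(s: str, dialect: str = "iso") -> datetime:
    if dialect == "canonical":
        return parse_datetime(s, strict=False)
    if dialect == "iso":
        return datetime.fromisoformat(s).replace(second=0, microsecond=0)
    raise ValueError(f"unknown DateTime dialect {dialect!r}")


def read_notes_table(
    path: str | Path,
    dialect: str = "iso",
    column_map: Optional[Dict[str, str]] = None,
) -> List[ClinicalNote]:
    """Read a notes table into :class:`ClinicalNote` records.

    ``column_map`` maps the required names (note_id, note_type,
    note_datetime, text) onto arbitrary source headers.  Raises
    :class:`SchemaError` for a missing column and :class:`RowError`
    (with the row number) for an unparseable DateTime or note type.
    """
    df = _read_table(path)
    column_map = column_map or {}
    resolved = {c: column_map.get(c, c) for c in NOTE_COLUMNS}
    for want, have in resolved.items():
        if have not in df.columns:
            raise SchemaError(f"missing required column {have!r} (for {want})")
    notes = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        raw_type = str(rec[resolved["note_type"]]).strip().upper()
        note_type = _NOTE_TYPE_ALIASES.get(raw_type)
        if note_type is None:
            raise RowError(f"unknown note type {rec[resolved['note_type']]!r}", i)
        try:
            note_dt = parse_note_datetime(str(rec[resolved["note_datetime"]]), dialect)
        except ValueError as exc:
            raise RowError(f"unparseable note_datetime: {exc}", i) from exc
        notes.append(
            ClinicalNote(
                note_id=str(rec[resolved["note_id"]]),
                note_type=note_type,
                note_datetime=note_dt,
                text=str(rec[resolved["text"]]),
            )
        )
    return notes


def read_annotations_table(
    path: str | Path,
    dialect: str = "iso",
    column_map: Optional[Dict[str, str]] = None,
) -> List[OnsetAnnotation]:
    """Read gold annotations; enforces at most one annotation per note."""
    df = _read_table(path)
    column_map = column_map or {}
    resolved = {c: column_map.get(c, c) for c in ANNOTATION_COLUMNS}
    for want, have in resolved.items():
        if have not in df.columns:
            raise SchemaError(f"missing required column {have!r} (for {want})")
    annotations: List[OnsetAnnotation] = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        note_id = str(rec[resolved["note_id"]])
        if note_id in seen:
            raise RowError(f"duplicate annotation for note_id {note_id!r}", i)
        seen.add(note_id)
        try:
            onset = parse_note_datetime(str(rec[resolved["onset_datetime"]]), dialect)
        except ValueError as exc:
            raise RowError(f"unparseable onset_datetime: {exc}", i) from exc
        annotations.append(OnsetAnnotation(note_id=note_id, gold_onset=onset))
    return annotations


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".tsv":
        df.to_csv(path, sep="\t", index=False)
    elif path.suffix.lower() in (".xlsx", ".xls"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# JSON-per-note results

def _expression_record(expr: Optional[TimeExpression]) -> Optional[dict]:
    if expr is None:
        return None
    rec = {
        "span": list(expr.span),
        "raw": expr.raw,
        "kind": expr.kind.value,
        "format_category": expr.format_category.value,
    }
    for name in ("hour", "minute", "offset_quantity", "rel_word",
                 "month", "day", "year"):
        value = getattr(expr, name)
        if value is not None:
            rec[name] = value
    if expr.meridiem is not None:
        rec["meridiem"] = expr.meridiem.value
    if expr.offset_unit is not None:
        rec["offset_unit"] = expr.offset_unit.value
    if expr.endpoints is not None:
        rec["endpoints"] = [_expression_record(e) for e in expr.endpoints]
    return rec


def _expression_from_record(rec: Optional[dict]) -> Optional[TimeExpression]:
    if rec is None:
        return None
    endpoints = None
    if "endpoints" in rec:
        endpoints = tuple(_expression_from_record(e) for e in rec["endpoints"])
    meridiem = Meridiem(rec["meridiem"]) if "meridiem" in rec else None
    offset_unit = OffsetUnit(rec["offset_unit"]) if "offset_unit" in rec else None
    return TimeExpression(
        tuple(rec["span"]), rec["raw"], ExpressionKind(rec["kind"]),
        hour=rec.get("hour"), minute=rec.get("minute"), meridiem=meridiem,
        offset_quantity=rec.get("offset_quantity"), offset_unit=offset_unit,
        format_category=FormatCategory(rec["format_category"]),
        rel_word=rec.get("rel_word"), month=rec.get("month"),
        day=rec.get("day"), year=rec.get("year"), endpoints=endpoints,
    )


def result_record(
    result: ExtractionResult, expressions: Sequence[TimeExpression]
) -> dict:
    """JSON-serializable record for one note's extraction."""
    return {
        "note_id": result.note_id,
        "note_type": result.note_type.value if result.note_type else None,
        "mode": result.mode,
        "n_outputs": result.n_outputs,
        "resolved": result.resolved.formatted if result.resolved else None,
        "outputs": [
            {
                "stage": o.stage.value,
                "formatted": o.formatted,
                "expression": _expression_record(o.expression),
            }
            for o in result.outputs
        ],
        "expressions": [_expression_record(e) for e in expressions],
    }


def write_results_jsonl(records: Sequence[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def read_results_jsonl(
    path: str | Path,
) -> Tuple[List[ExtractionResult], Dict[str, List[TimeExpression]]]:
    """Rebuild results (and per-note expressions) from a JSONL file."""
    results: List[ExtractionResult] = []
    expressions: Dict[str, List[TimeExpression]] = {}
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            outputs = [
                NormalizedOnset(
                    _expression_from_record(o["expression"]),
                    parse_datetime(o["formatted"]),
                    Stage(o["stage"]),
                )
                for o in rec["outputs"]
            ]
            resolved = None
            if rec["resolved"] is not None:
                resolved = next(
                    (o for o in outputs if o.formatted == rec["resolved"]), None
                )
            results.append(
                ExtractionResult(
                    note_id=rec["note_id"],
                    outputs=outputs,
                    n_outputs=rec["n_outputs"],
                    mode=rec["mode"],
                    note_type=NoteType(rec["note_type"]) if rec["note_type"] else None,
                    resolved=resolved,
                )
            )
            expressions[rec["note_id"]] = [
                _expression_from_record(e) for e in rec["expressions"]
                if e is not None
            ]
    return results, expressions


# ---------------------------------------------------------------------------
# pipeline driver

def extract_note(
    note: ClinicalNote, pipeline: str, mode: str, run_both: bool = False
) -> Tuple[ExtractionResult, List[TimeExpression]]:
    """Run one pipeline on one note, returning the result and the raw
    detected expressions (which, for the pattern pipeline in faithful
    mode, exist even though no anchored outputs do)."""
    if pipeline == "hybrid":
        result = hybrid.extract_onsets(note, mode, run_both=run_both)
        exprs = [o.expression for o in result.outputs if o.expression is not None]
        return result, exprs
    if pipeline == "regex":
        exprs = regexsuite.extract_expressions_regex(note.text)
        outputs = regexsuite.anchor_regex_outputs(
            exprs, note.note_datetime, mode, note.text
        )
        result = ExtractionResult(
            note_id=note.note_id,
            outputs=outputs,
            n_outputs=len(outputs),
            mode=mode,
            note_type=note.note_type,
        )
        return result, exprs
    raise ValueError(f"unknown pipeline {pipeline!r}")


def run_extract(
    notes_path: str | Path,
    pipeline: str,
    mode: str,
    out_path: str | Path,
    dialect: str = "iso",
    run_both: bool = False,
    column_map: Optional[Dict[str, str]] = None,
) -> dict:
    """Extract onsets for every note in a table; write JSONL; return a summary."""
    notes = read_notes_table(notes_path, dialect=dialect, column_map=column_map)
    records = []
    n_outputs_total = 0
    notes_with_output = 0
    for note in notes:
        result, exprs = extract_note(note, pipeline, mode, run_both)
        records.append(result_record(result, exprs))
        n_outputs_total += result.n_outputs
        notes_with_output += int(result.n_outputs > 0)
    write_results_jsonl(records, out_path)
    summary = {
        "n_notes": len(notes),
        "pipeline": pipeline,
        "mode": mode,
        "n_outputs_total": n_outputs_total,
        "notes_with_output": notes_with_output,
    }
    logger.info("extracted %(n_outputs_total)d outputs from %(n_notes)d notes", summary)
    return summary


def example_notes_path() -> Path:
    """Path to the bundled fixture of worked example sentences."""
    from importlib import resources

    return Path(str(resources.files("onsetdt.data").joinpath("example_notes.csv")))
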