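"""Match-based evaluation against expert-annotated gold onsets.

A note counts as matched when any of its canonical ``MM/DD/YYYY HH:MM``
outputs equals the gold onset rendered the same way (semantic DateTime
equality at minute precision; an optional minute tolerance exists but is
off by default).  Reports tabulate, per note type, the joint distribution
of matched status and output count, and separately the format categories
of the extracted expressions with example strings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import timedelta
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .hybrid import ExtractionResult
from .types import NoteType, OnsetAnnotation, TimeExpression


class PairingError(KeyError):
    """Results and gold annotations could not be paired by note_id."""


def match_note(
    result: ExtractionResult,
    gold: OnsetAnnotation,
    tolerance_minutes: int = 0,
) -> Tuple[int, int]:
    """Return ``(matched, n_outputs)`` for one note.

    ``matched`` is 1 iff any output equals the gold onset at minute
    precision (within ``tolerance_minutes``, default exact).  A note with
    several matching outputs still counts as matched once.
    """
    if result.note_id != gold.note_id:
        raise PairingError(
            f"result note_id {result.note_id!r} != gold note_id {gold.note_id!r}"
        )
    tol = timedelta(minutes=tolerance_minutes)
    matched = int(
        any(abs(o.onset - gold.gold_onset) <= tol for o in result.outputs)
    )
    return matched, result.n_outputs


@dataclass
class MatchReport:
    """Tabulated evaluation of a batch of notes.

    ``grid`` counts notes by (note_type, matched, n_outputs) and always
    sums to the number of evaluated notes; ``format_table`` counts
    extracted expressions per format category (with example strings) and
    sums to the total expression count.
    """

    rows: List[dict]
    grid: Dict[Tuple[str, int, int], int]
    format_table: Dict[str, dict]
    totals: dict

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "grid": [
                {"note_type": nt, "matched": m, "n_outputs": n, "count": c}
                for (nt, m, n), c in sorted(self.grid.items())
            ],
            "format_table": self.format_table,
            "totals": self.totals,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def outputs_table(self) -> pd.DataFrame:
        """Matched-status x output-count distribution, one column per note type."""
        note_types = [t.value for t in NoteType]
        records = []
        for matched in (0, 1):
            counts = {
                (nt, n): c for (nt, m, n), c in self.grid.items() if m == matched
            }
            for n in sorted({n for (_, n) in counts}):
                rec = {
                    "matched": matched,
                    "n_outputs": n,
                    "total": sum(c for (nt, nn), c in counts.items() if nn == n),
                }
                for nt in note_types:
                    rec[nt] = counts.get((nt, n), 0)
                records.append(rec)
        cols = ["matched", "n_outputs", "total", *note_types]
        return pd.DataFrame.from_records(records, columns=cols)

    def formats_table(self) -> pd.DataFrame:
        """Expression format categories with counts and example strings."""
        records = [
            {
                "format": cat,
                "count": info["count"],
                "examples": ", ".join(info["examples"]),
            }
            for cat, info in self.format_table.items()
        ]
        return pd.DataFrame.from_records(
            records, columns=["format", "count", "examples"]
        )


_MAX_EXAMPLES = 5


def tabulate(
    results: Sequence[ExtractionResult],
    golds: Iterable[OnsetAnnotation] | Mapping[str, OnsetAnnotation],
    expressions: Optional[Mapping[str, Sequence[TimeExpression]]] = None,
    tolerance_minutes: int = 0,
) -> MatchReport:
    """Build a :class:`MatchReport` from per-note results and gold onsets.

    ``expressions`` optionally supplies the detected expressions per note
    for the format table (needed for pipelines whose faithful mode emits
    expressions but no anchored outputs); otherwise the source expressions
    of the anchored outputs are tabulated.  The report is order-invariant.
    """
    if not isinstance(golds, Mapping):
        golds = {g.note_id: g for g in golds}
    missing = [r.note_id for r in results if r.note_id not in golds]
    if missing:
        raise PairingError(f"no gold annotation for note_ids: {missing}")

    rows: List[dict] = []
    grid: Dict[Tuple[str, int, int], int] = {}
    for r in sorted(results, key=lambda r: str(r.note_id)):
        matched, n_outputs = match_note(r, golds[r.note_id], tolerance_minutes)
        note_type = r.note_type.value if r.note_type else "UNKNOWN"
        rows.append(
            {
                "note_id": r.note_id,
                "note_type": note_type,
                "n_outputs": n_outputs,
                "matched": matched,
            }
        )
        key = (note_type, matched, n_outputs)
        grid[key] = grid.get(key, 0) + 1

    if expressions is None:
        expressions = {
            r.note_id: [o.expression for o in r.outputs if o.expression is not None]
            for r in results
        }
    format_table: Dict[str, dict] = {}
    for note_id in sorted(expressions, key=str):
        for expr in expressions[note_id]:
            cat = expr.format_category.value
            info = format_table.setdefault(cat, {"count": 0, "examples": []})
            info["count"] += 1
            if len(info["examples"]) < _MAX_EXAMPLES and expr.raw not in info["examples"]:
                info["examples"].append(expr.raw)

    n_notes = len(results)
    totals = {
        "n_notes": n_notes,
        "n_matched": sum(row["matched"] for row in rows),
        "n_expressions": sum(info["count"] for info in format_table.values()),
    }
    assert sum(grid.values()) == n_notes
    return MatchReport(rows=rows, grid=grid, format_table=format_table, totals=totals)
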