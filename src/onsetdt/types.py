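"""Shared data model for onset DateTime extraction.

The package's canonical output format is the month-first, zero-padded
``MM/DD/YYYY HH:MM`` string used for matching against expert-annotated
gold onsets.  All date-times are timezone-naive at minute precision;
seconds are truncated on construction.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional, Tuple


class NoteType(str, enum.Enum):
    """Clinical note categories seen in emergency chest-pain workflows."""

    HP = "HP"                # History & Physical
    TRIAGE = "TRIAGE"        # free-narrative triage note
    ED_SCREEN = "ED_SCREEN"  # ED screening / first contact


class ExpressionKind(str, enum.Enum):
    CLOCK_HHMM = "clock_hhmm"          # colon-separated 24-hour time, e.g. 20:30
    CLOCK_AMPM = "clock_ampm"          # 12-hour time with (or awaiting) am/pm
    MILITARY = "military"              # 4-digit HHMM, e.g. 0530
    DAYPART = "daypart"                # vague period word: morning, evening, ...
    WAKE_PHRASE = "wake_phrase"        # woke / awoke / awakened from sleep
    RELATIVE_OFFSET = "relative_offset"  # "2 days ago", "four hours ago"
    RANGE = "range"                    # "0200-0300", "2-3 days ago"
    PARTIAL_DATE = "partial_date"      # "03/20", "Mar 2, 2016"
    YEAR = "year"                      # standalone 4-digit year
    RELATIVE_WORD = "relative_word"    # yesterday, today, last night, ...


class Meridiem(str, enum.Enum):
    AM = "am"
    PM = "pm"


class OffsetUnit(str, enum.Enum):
    HOUR = "hour"
    DAY = "day"
    WEEK = "week"
    # calendar-month offsets are an extension beyond the published day/week rules
    MONTH = "month"


class FormatCategory(str, enum.Enum):
    """Format labels used when tabulating extracted expressions."""

    HHMM_COLON = "HHMM_COLON"
    HH_AMPM = "HH_AMPM"
    MILITARY = "MILITARY"
    HOUR_PLUS_RELATIVE = "HOUR_PLUS_RELATIVE"
    YYYY = "YYYY"
    OTHER = "OTHER"


class Stage(str, enum.Enum):
    PRIMARY = "primary"
    FALLBACK = "fallback"
    LEXICON = "lexicon"


class CanonicalFormatError(ValueError):
    """Raised when a string does not parse as canonical ``MM/DD/YYYY HH:MM``."""

    def __init__(self, message: str, fieldname: str):
        super().__init__(message)
        self.fieldname = fieldname


def _truncate_to_minute(dt: datetime) -> datetime:
    return dt.replace(second=0, microsecond=0)


def format_datetime(dt: datetime) -> str:
    """Render ``dt`` in the canonical zero-padded ``MM/DD/YYYY HH:MM`` form.

    Seconds and finer are truncated; the rendering is the exact inverse of
    :func:`parse_datetime`.

    >>> format_datetime(datetime(1999, 12, 31, 8, 35))
    '12/31/1999 08:35'
    """
    return _truncate_to_minute(dt).strftime("%m/%d/%Y %H:%M")


_STRICT_RE = re.compile(r"^(\d{2})/(\d{2})/(\d{4}) (\d{2}):(\d{2})$")
_LENIENT_RE = re.compile(r"^(\d{1,2})/(\d{1,2})/(\d{4})\s+(\d{1,2}):(\d{1,2})$")


def parse_datetime(s: str, strict: bool = True) -> datetime:
    """Parse a canonical ``MM/DD/YYYY HH:MM`` string.

    In strict mode (the default, used by the match-based evaluation) every
    field must be zero-padded; the lenient mode accepts one-digit fields.

    Raises
    ------
    CanonicalFormatError
        Naming the offending field (``shape`` when the overall pattern does
        not match, else ``month``/``day``/``hour``/``minute``).
    """
    rx = _STRICT_RE if strict else _LENIENT_RE
    m = rx.match(s)
    if m is None:
        raise CanonicalFormatError(
            f"{s!r} does not match canonical MM/DD/YYYY HH:MM"
            + ("" if not strict else " (zero-padded)"),
            "shape",
        )
    month, day, year, hour, minute = (int(g) for g in m.groups())
    for name, val, lo, hi in (
        ("month", month, 1, 12),
        ("hour", hour, 0, 23),
        ("minute", minute, 0, 59),
    ):
        if not lo <= val <= hi:
            raise CanonicalFormatError(f"invalid {name} {val} in {s!r}", name)
    try:
        return datetime(year, month, day, hour, minute)
    except ValueError as exc:
        raise CanonicalFormatError(f"invalid day {day} in {s!r}", "day") from exc


@dataclass
class ClinicalNote:
    """A clinical note plus the reference DateTime it was written at."""

    note_id: str
    note_type: NoteType
    note_datetime: datetime
    text: str

    def __post_init__(self) -> None:
        self.note_type = NoteType(self.note_type)
        if not isinstance(self.note_datetime, datetime):
            raise TypeError("note_datetime must be a datetime")
        if self.note_datetime.tzinfo is not None:
            raise ValueError("note_datetime must be timezone-naive")
        self.note_datetime = _truncate_to_minute(self.note_datetime)


@dataclass
class TimeExpression:
    """A temporal expression detected in note text.

    ``span`` is a 0-based half-open character interval into the note text
    and ``raw`` is exactly ``text[start:end]``.  Parsed components are
    optional: a daypart word has neither hour nor minute; a 12-hour clock
    time awaiting meridiem inference has an hour but no meridiem.
    """

    span: Tuple[int, int]
    raw: str
    kind: ExpressionKind
    hour: Optional[int] = None
    minute: Optional[int] = None
    meridiem: Optional[Meridiem] = None
    offset_quantity: Optional[int] = None
    offset_unit: Optional[OffsetUnit] = None
    format_category: Optional[FormatCategory] = None
    # auxiliary parse products
    rel_word: Optional[str] = None             # normalized relative word, if compound
    month: Optional[int] = None                # partial/full date components
    day: Optional[int] = None
    year: Optional[int] = None
    endpoints: Optional[Tuple["TimeExpression", "TimeExpression"]] = None

    def __post_init__(self) -> None:
        start, end = self.span
        if not 0 <= start < end:
            raise ValueError(f"invalid span {self.span}")
        if self.hour is not None and not 0 <= self.hour <= 23:
            raise ValueError(f"hour out of range: {self.hour}")
        if self.minute is not None and not 0 <= self.minute <= 59:
            raise ValueError(f"minute out of range: {self.minute}")
        if self.kind is ExpressionKind.RANGE and (
            self.endpoints is None or len(self.endpoints) != 2
        ):
            raise ValueError("range expression requires two endpoints")
        if self.format_category is None:
            self.format_category = format_category_for(self)

    def check_against(self, text: str) -> None:
        """Assert the span/raw invariant against the owning note text."""
        start, end = self.span
        if not 0 <= start < end <= len(text):
            raise ValueError(f"span {self.span} outside text of length {len(text)}")
        if text[start:end] != self.raw:
            raise ValueError(
                f"raw {self.raw!r} != text[{start}:{end}] {text[start:end]!r}"
            )


def format_category_for(expr: TimeExpression) -> FormatCategory:
    """Assign the tabulation format category of a detected expression.

    Total and deterministic: every expression gets exactly one category.
    A clock time combined with a relative word ("0530 today", "9 pm last
    night") counts as one HOUR_PLUS_RELATIVE expression.
    """
    clockish = expr.kind in (
        ExpressionKind.CLOCK_HHMM,
        ExpressionKind.CLOCK_AMPM,
        ExpressionKind.MILITARY,
    )
    if clockish and expr.rel_word is not None:
        return FormatCategory.HOUR_PLUS_RELATIVE
    if expr.kind is ExpressionKind.CLOCK_AMPM and expr.meridiem is not None:
        return FormatCategory.HH_AMPM
    if expr.kind is ExpressionKind.CLOCK_HHMM:
        return FormatCategory.HHMM_COLON
    if expr.kind is ExpressionKind.MILITARY:
        return FormatCategory.MILITARY
    if expr.kind is ExpressionKind.YEAR:
        return FormatCategory.YYYY
    return FormatCategory.OTHER


@dataclass
class NormalizedOnset:
    """An absolute onset DateTime with provenance.

    ``formatted`` is always the canonical rendering of ``onset`` and is
    recomputed on construction, so the two can never disagree.
    """

    expression: Optional[TimeExpression]
    onset: datetime
    stage: Stage
    formatted: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.onset = _truncate_to_minute(self.onset)
        self.formatted = format_datetime(self.onset)


@dataclass(frozen=True)
class OnsetAnnotation:
    """Expert-annotated gold onset DateTime for one note."""

    note_id: str
    gold_onset: datetime

    def __post_init__(self) -> None:
        object.__setattr__(self, "gold_onset", _truncate_to_minute(self.gold_onset))
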