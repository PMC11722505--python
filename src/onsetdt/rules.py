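"""Rules for unspecified symptom-onset times.

Implements the AHA-derived rule system used when a note does not state an
explicit onset time: a daypart/wake-phrase lexicon mapping vague period
words to fixed clock times, backward relative-offset arithmetic ("2 days
ago" keeps the note's clock time), range resolution (the endpoint closest
to, and not after, the note DateTime wins), and the most-recent-episode
rule for intermittent symptoms.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass
from datetime import datetime, time, timedelta
from importlib import resources
from typing import Iterable, List, Optional, Sequence

from dateutil.relativedelta import relativedelta

from .types import OffsetUnit, TimeExpression

logger = logging.getLogger(__name__)

MIN_YEAR = 1900
#: Offsets beyond this many days are resolved but flagged in the log:
#: the published day-offset rule is only illustrated up to 4 days.
FLAG_OFFSET_DAYS = 30


class RuleSource(str, enum.Enum):
    AHA = "AHA"
    EXTENDED = "EXTENDED"


class FlaggedResultError(ValueError):
    """No candidate onset lies at or before the note DateTime."""


class OffsetRangeError(ValueError):
    """Relative-offset arithmetic left the supported calendar range."""


@dataclass(frozen=True)
class RuleLexiconEntry:
    phrase: str
    clock_time: time
    source: RuleSource


def _load_lexicon() -> List[RuleLexiconEntry]:
    entries = []
    raw = resources.files("onsetdt.data").joinpath("onset_lexicon.tsv").read_text()
    for line in raw.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        phrase, clock, source = line.split("\t")
        hh, mm = clock.split(":")
        entries.append(
            RuleLexiconEntry(phrase, time(int(hh), int(mm)), RuleSource(source))
        )
    return entries


#: The versioned daypart/wake lexicon, loaded from the package data table.
LEXICON: List[RuleLexiconEntry] = _load_lexicon()
_LEXICON_BY_PHRASE = {e.phrase: e.clock_time for e in LEXICON}

# Surface variants normalized onto canonical lexicon phrases.  Wake verbs
# with no morning context fall under the awaken-from-sleep rule; "woke up"
# adjacent to "morning" is the later, deliberate wake-up rule.
_VARIANTS = {
    "woke": "awaken from sleep",
    "woke up": "awaken from sleep",
    "awoke": "awaken from sleep",
    "awakened": "awaken from sleep",
    "awoken": "awaken from sleep",
    "awakened from sleep": "awaken from sleep",
    "awoke from sleep": "awaken from sleep",
    "woke up from sleep": "awaken from sleep",
    "woke from sleep": "awaken from sleep",
    "woke up in the morning": "wake up in the morning",
    "woke up this morning": "wake up in the morning",
    "awoke this morning": "wake up in the morning",
    "woke this morning": "wake up in the morning",
    "mid morning": "midmorning",
    "mid-morning": "midmorning",
    "lunchtime": "lunch time",
    "lunch": "lunch time",
    "noon": "lunch time",
    "dinnertime": "dinner time",
    "dinner": "dinner time",
    "supper": "dinner time",
    "tonight": "evening",
    "last night": "evening",
    "last evening": "evening",
    "overnight": "evening",
}

_PRONOUN_RE = re.compile(r"^(?:he|she|they|pt|patient|says)\s+", re.IGNORECASE)
_LEADIN_RE = re.compile(r"^(?:this|the|in the|at|around|since|early)\s+")


def _normalize_phrase(phrase: str) -> str:
    s = re.sub(r"[^a-z\- ]+", " ", phrase.lower())
    s = re.sub(r"\s+", " ", s).strip()
    while True:
        t = _PRONOUN_RE.sub("", s)
        if t == s:
            break
        s = t
    return s


def lookup_daypart(phrase: str) -> Optional[time]:
    """Return the lexicon clock time triggered by ``phrase``, if any.

    Matching is case-insensitive and whitespace-normalized, tolerates
    leading pronouns/determiners ("he woke", "this morning"), and covers
    wake-verb variants.  Returns ``None`` when no trigger matches.

    >>> lookup_daypart("morning")
    datetime.time(7, 0)
    >>> lookup_daypart("AWAKEN FROM SLEEP")
    datetime.time(3, 0)
    """
    s = _normalize_phrase(phrase)
    for candidate in (s, _LEADIN_RE.sub("", s)):
        if candidate in _VARIANTS:
            candidate = _VARIANTS[candidate]
        if candidate in _LEXICON_BY_PHRASE:
            return _LEXICON_BY_PHRASE[candidate]
    return None


def resolve_relative_offset(
    quantity: int, unit: OffsetUnit | str, note_dt: datetime
) -> datetime:
    """Step ``quantity`` units backward from the note DateTime.

    Day and week offsets preserve the note's clock time (the "same hour
    time with 24-hour increment backward" rule; a week is 7 days).  Month
    offsets use calendar-month arithmetic with day-of-month clamping — an
    extension beyond the published rules.

    >>> resolve_relative_offset(1, "day", datetime(2000, 1, 1, 8, 35))
    datetime.datetime(1999, 12, 31, 8, 35)
    """
    if quantity < 0:
        raise ValueError("offset quantity must be non-negative")
    unit = OffsetUnit(unit)
    if unit is OffsetUnit.HOUR:
        result = note_dt - timedelta(hours=quantity)
    elif unit is OffsetUnit.DAY:
        result = note_dt - timedelta(days=quantity)
    elif unit is OffsetUnit.WEEK:
        result = note_dt - timedelta(weeks=quantity)
    else:
        result = note_dt - relativedelta(months=quantity)
    if result.year < MIN_YEAR:
        raise OffsetRangeError(
            f"offset of {quantity} {unit.value}(s) from {note_dt} precedes {MIN_YEAR}"
        )
    in_days = (note_dt - result).days
    if in_days > FLAG_OFFSET_DAYS:
        logger.warning(
            "relative offset of %d day(s) exceeds the %d-day illustrated range",
            in_days,
            FLAG_OFFSET_DAYS,
        )
    return result


def anchor_clock(hour: int, minute: int, note_dt: datetime) -> datetime:
    """Place a clock time on the note's day, or the previous day.

    Onset precedes presentation: the note's calendar day is used when that
    yields a DateTime at or before the note DateTime, otherwise the
    previous day.
    """
    candidate = note_dt.replace(hour=hour, minute=minute, second=0, microsecond=0)
    if candidate > note_dt:
        candidate -= timedelta(days=1)
    return candidate


def anchor_endpoint(endpoint: TimeExpression, note_dt: datetime) -> datetime:
    """Anchor a range endpoint: a resolved clock time or a backward offset."""
    if endpoint.offset_quantity is not None and endpoint.offset_unit is not None:
        return resolve_relative_offset(
            endpoint.offset_quantity, endpoint.offset_unit, note_dt
        )
    if endpoint.hour is None:
        raise ValueError(f"range endpoint {endpoint.raw!r} is not resolvable")
    hour = endpoint.hour
    if endpoint.meridiem is not None:
        hour = hour % 12 + (12 if endpoint.meridiem.value == "pm" else 0)
    return anchor_clock(hour, endpoint.minute or 0, note_dt)


def resolve_range(
    endpoint_a: TimeExpression,
    endpoint_b: TimeExpression,
    note_dt: datetime,
) -> TimeExpression:
    """Pick the range endpoint closest to (and not after) the note DateTime.

    Assuming intermittent symptoms, the most recent candidate wins: for a
    clock-time range ("0200–0300") that is the later clock time; for an
    "ago" range ("2–3 days ago") the smaller offset.

    Raises
    ------
    FlaggedResultError
        If neither endpoint anchors at or before the note DateTime.
    """
    anchored = [
        (anchor_endpoint(e, note_dt), e) for e in (endpoint_a, endpoint_b)
    ]
    eligible = [(dt, e) for dt, e in anchored if dt <= note_dt]
    if not eligible:
        raise FlaggedResultError(
            f"neither range endpoint anchors before note DateTime {note_dt}"
        )
    return max(eligible, key=lambda pair: pair[0])[1]


def select_most_recent(
    candidates: Sequence[datetime] | Iterable[datetime], note_dt: datetime
) -> datetime:
    """Most recent candidate onset at or before the note DateTime.

    Implements the intermittent-symptom rule: of several episodes, the most
    recent onset prior to hospital presentation is the one reported.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidates must be non-empty")
    eligible = [c for c in candidates if c <= note_dt]
    if not eligible:
        raise FlaggedResultError(
            f"all candidate onsets fall after note DateTime {note_dt}"
        )
    return max(eligible)
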