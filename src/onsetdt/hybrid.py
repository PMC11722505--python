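"""Hybrid DateTime extraction pipeline.

The primary scanner recognizes human-readable temporal phrases — relative
words ("yesterday", "last night"), backward offsets ("2 days ago"), clock
times with meridiem ("9 pm"), compound phrases ("last night at 9 pm",
"3AM today"), partial dates, and the daypart/wake triggers of the onset
lexicon.  When the primary scan finds nothing, a fallback scanner hunts
for explicit numeric times, correcting punctuation ("4.45 am" -> "4:45 am")
and inferring a missing meridiem from daypart context or from the latest
anchoring at or before the note DateTime.  Every detected expression is
then anchored to an absolute onset DateTime against the note's reference
DateTime.

Two modes are provided.  ``faithful`` reproduces the behavior of a naive
off-the-shelf parse: no deduplication (a note can yield several identical
outputs) and no guard against distractor numerics such as medication
doses.  ``extended`` guards distractors, deduplicates, drops anchors after
the note DateTime, and resolves multiple candidates with the
most-recent-episode rule.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Callable, List, Optional, Tuple

from . import rules
from .types import (
    ClinicalNote,
    ExpressionKind,
    Meridiem,
    NormalizedOnset,
    NoteType,
    OffsetUnit,
    Stage,
    TimeExpression,
)

logger = logging.getLogger(__name__)

Mode = str  # "faithful" | "extended"

# ---------------------------------------------------------------------------
# token fragments (all patterns compiled case-insensitively)

_AMPM = r"[ap]\.?m\.?(?![a-z0-9])"
_CLOCK12 = rf"(?:1[0-2]|0?[1-9])(?::[0-5]\d)?\s*{_AMPM}"
_HHMM = r"(?<![\d:.])(?:[01]?\d|2[0-3]):[0-5]\d(?![\d:])"
_MIL = r"(?<![\d:/.])(?:[01]\d|2[0-3])[0-5]\d(?![\d:/])"
_CLOCKANY = rf"(?:{_CLOCK12}|{_HHMM}|{_MIL})"

_REL = (
    r"(?:last\s+night|last\s+evening|yesterday\s+morning|yesterday\s+evening|"
    r"this\s+morning|this\s+evening|this\s+afternoon|tonight|today|yesterday|"
    r"next\s+week)"
)

_NUM_WORDS = {
    "one": 1, "two": 2, "three": 3, "four": 4, "five": 5, "six": 6,
    "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11, "twelve": 12,
    "a": 1, "an": 1, "a couple of": 2,
}
_NUMTOK = r"(?:\d+|a couple of|one|two|three|four|five|six|seven|eight|nine|ten|eleven|twelve|an?)"

_RANGE_SEP = r"(?:\s*[-–—]\s*|\s+(?:to|or)\s+)"

#: unit/count tokens that disqualify a bare numeral from being a time
DISTRACTOR_UNITS = frozenset(
    """mg mcg g gm ml cc l lpm mmhg stent stents nitro nitros tab tabs tablet
    tablets pill pills dose doses puff puffs spray sprays unit units x times
    yo y/o yr yrs year years old lb lbs kg % min mins minute minutes hour
    hours hr hrs day days week weeks wk wks month months""".split()
)

_cue = r"(?:since|at|around|about|until|till|approx\w*\.?|@|by)"


def _c(pattern: str) -> re.Pattern:
    return re.compile(pattern, re.IGNORECASE)


_P_RANGE_OFFSET = _c(
    rf"\b(?P<q1>\d+){_RANGE_SEP}(?P<q2>\d+)\s+(?P<u>hour|day|week|month)s?\s+ago\b"
)
_P_RANGE_CLOCK = _c(rf"(?P<c1>{_CLOCKANY}){_RANGE_SEP}(?P<c2>{_CLOCKANY})")
_P_COMPOUND_RC = _c(
    rf"\b(?P<rel>{_REL})\s*(?:,?\s*(?:at|around|about|approx\w*\.?)\s+)?(?P<clock>{_CLOCKANY})"
)
_P_COMPOUND_CR = _c(rf"(?P<clock>{_CLOCKANY})\s+(?:on\s+)?(?P<rel>{_REL})\b")
_P_CLOCK12 = _c(rf"(?<![\d:.])(?P<h>1[0-2]|0?[1-9])(?::(?P<m>[0-5]\d))?\s*(?P<mer>{_AMPM})")
_P_HHMM = _c(rf"(?P<t>{_HHMM})")
_P_MIL = _c(rf"(?P<t>{_MIL})")
_P_OFFSET = _c(rf"\b(?P<q>{_NUMTOK})\s+(?P<u>hour|day|week|month)s?\s+ago\b")
_P_WAKE = _c(
    r"\b(?:(?:he|she|they|pt|patient)\s+)?"
    r"(?:awakened?\s+from\s+sleep|awoke\s+from\s+sleep|"
    r"wok(?:e|en)\s+(?:up\s+)?from\s+sleep|"
    r"(?:woke|awoke)(?:\s+up)?\s+(?:in\s+the\s+morning|this\s+morning)|"
    r"wake\s+up\s+in\s+the\s+morning|woke\s+up|woke|awoke|awakened)\b"
)
_P_DAYPART = _c(
    r"\b(?:mid-?\s?morning|after\s+lunch|after\s+dinner|lunch\s?time|"
    r"dinner\s?time|morning|afternoon|evening|noon)\b"
)
_P_REL = _c(rf"\b(?P<rel>{_REL})\b")
_P_PDATE = _c(
    r"(?<![\d/.])(?P<mo>0?[1-9]|1[0-2])/(?P<d>0?[1-9]|[12]\d|3[01])"
    r"(?:/(?P<y>\d{4}|\d{2}))?(?![\d/])"
)
_P_MONTHNAME = _c(
    r"\b(?P<mon>jan(?:uary)?|feb(?:ruary)?|mar(?:ch)?|apr(?:il)?|may|jun(?:e)?|"
    r"jul(?:y)?|aug(?:ust)?|sep(?:t|tember)?|oct(?:ober)?|nov(?:ember)?|"
    r"dec(?:ember)?)\.?\s+(?P<d>\d{1,2})(?:,?\s+(?P<y>\d{4}))?\b"
)
_P_BARE = _c(r"(?<![\d:./])(?P<h>1[0-2]|[1-9])(?![\d:./])")
_P_MIL_CUE = _c(rf"\b{_cue}\s+(?P<t>{_MIL})")
_P_DOTTIME = _c(
    rf"(?<![\d:.])(?P<h>1[0-2]|0?[1-9])\.(?P<m>[0-5]\d)(?!\d)(?P<mer>\s*{_AMPM})?"
)
_P_BARE_CUE = _c(rf"\b{_cue}\s+(?P<h>1[0-2]|0?[1-9])\b(?![\d:./])")

_MONTHS = {m: i + 1 for i, m in enumerate(
    "jan feb mar apr may jun jul aug sep oct nov dec".split()
)}


def _followed_by_unit(text: str, end: int) -> bool:
    m = re.match(r"[\s,]*(?:of\s+)?([a-z/%]+)", text[end:end + 24], re.IGNORECASE)
    return bool(m) and m.group(1).lower() in DISTRACTOR_UNITS


def _parse_clock_token(tok: str) -> TimeExpression:
    """Parse a clock token into a (span-less) expression skeleton."""
    m = _P_CLOCK12.match(tok)
    if m and m.end() == len(tok.rstrip()):
        mer = Meridiem.PM if m.group("mer").lower().startswith("p") else Meridiem.AM
        return TimeExpression(
            (0, 1), tok, ExpressionKind.CLOCK_AMPM,
            hour=int(m.group("h")), minute=int(m.group("m") or 0), meridiem=mer,
        )
    if ":" in tok:
        hh, mm = tok.split(":")
        return TimeExpression(
            (0, 1), tok, ExpressionKind.CLOCK_HHMM, hour=int(hh), minute=int(mm)
        )
    return TimeExpression(
        (0, 1), tok, ExpressionKind.MILITARY, hour=int(tok[:2]), minute=int(tok[2:])
    )


def _clock_expr(span, raw, tok, rel=None) -> TimeExpression:
    skel = _parse_clock_token(tok.strip())
    return TimeExpression(
        span, raw, skel.kind, hour=skel.hour, minute=skel.minute,
        meridiem=skel.meridiem, rel_word=rel,
    )


def _norm_rel(word: str) -> str:
    return re.sub(r"\s+", " ", word.lower().strip())


# candidate = (start, end, priority, build() -> TimeExpression | None)
_Candidate = Tuple[int, int, int, Callable[[], Optional[TimeExpression]]]


def _scan(text: str, families) -> List[TimeExpression]:
    candidates: List[_Candidate] = []
    for prio, family in enumerate(families):
        pattern, build = family[0], family[1]
        spanfn = family[2] if len(family) > 2 else (lambda m: m.span())
        for m in pattern.finditer(text):
            start, end = spanfn(m)
            candidates.append((start, end, prio, (lambda mm=m, b=build: b(mm))))
    # leftmost-longest selection; family order breaks remaining ties
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0]), c[2]))
    chosen: List[TimeExpression] = []
    occupied_until = -1
    for start, end, _, build in candidates:
        if start < occupied_until:
            continue
        expr = build()
        if expr is None:
            continue
        chosen.append(expr)
        occupied_until = end
    return chosen


def parse_primary(
    text: str,
    note_dt: Optional[datetime] = None,
    *,
    guard_distractors: bool = True,
) -> List[TimeExpression]:
    """Scan for human-readable temporal phrases, in document order.

    With ``guard_distractors`` (the extended-mode default), bare numerals
    followed by unit or count tokens ("6 mg", "6 stents") are never time
    expressions; without it, standalone small integers are picked up as
    candidate hours, reproducing the classic misidentification failure of
    generic date parsers on clinical text.
    """

    def b_range_offset(m):
        u = OffsetUnit(m.group("u").lower())
        q1, q2 = int(m.group("q1")), int(m.group("q2"))
        mk = lambda q: TimeExpression(
            (0, 1), f"{q} {u.value}s ago", ExpressionKind.RELATIVE_OFFSET,
            offset_quantity=q, offset_unit=u,
        )
        return TimeExpression(
            m.span(), m.group(0), ExpressionKind.RANGE, endpoints=(mk(q1), mk(q2)),
        )

    def b_range_clock(m):
        a = _parse_clock_token(m.group("c1").strip())
        b = _parse_clock_token(m.group("c2").strip())
        return TimeExpression(
            m.span(), m.group(0), ExpressionKind.RANGE, endpoints=(a, b)
        )

    def b_compound(m):
        return _clock_expr(
            m.span(), m.group(0), m.group("clock"), rel=_norm_rel(m.group("rel"))
        )

    def b_clock12(m):
        mer = Meridiem.PM if m.group("mer").lower().startswith("p") else Meridiem.AM
        return TimeExpression(
            m.span(), m.group(0), ExpressionKind.CLOCK_AMPM,
            hour=int(m.group("h")), minute=int(m.group("m") or 0), meridiem=mer,
        )

    def b_hhmm(m):
        hh, mm = m.group("t").split(":")
        return TimeExpression(
            m.span(), m.group(0), ExpressionKind.CLOCK_HHMM,
            hour=int(hh), minute=int(mm),
        )

    def b_offset(m):
        qtok = m.group("q").lower()
        q = int(qtok) if qtok.isdigit() else _NUM_WORDS[qtok]
        return TimeExpression(
            m.span(), m.group(0), ExpressionKind.RELATIVE_OFFSET,
            offset_quantity=q, offset_unit=OffsetUnit(m.group("u").lower()),
        )

    def b_wake(m):
        return TimeExpression(m.span(), m.group(0), ExpressionKind.WAKE_PHRASE)

    def b_daypart(m):
        return TimeExpression(m.span(), m.group(0), ExpressionKind.DAYPART)

    def b_rel(m):
        return TimeExpression(
            m.span(), m.group(0), ExpressionKind.RELATIVE_WORD,
            rel_word=_norm_rel(m.group("rel")),
        )

    def b_pdate(m):
        y = m.group("y")
        if y is not None:
            y = int(y)
            y += 2000 if y < 70 else (1900 if y < 100 else 0)
        return TimeExpression(
            m.span(), m.group(0), ExpressionKind.PARTIAL_DATE,
            month=int(m.group("mo")), day=int(m.group("d")), year=y,
        )

    def b_monthname(m):
        y = m.group("y")
        return TimeExpression(
            m.span(), m.group(0), ExpressionKind.PARTIAL_DATE,
            month=_MONTHS[m.group("mon").lower()[:3]], day=int(m.group("d")),
            year=int(y) if y else None,
        )

    def b_bare(m):
        # faithful mode keeps the misread even before units; the
        # distractor guard is extended-mode only
        return TimeExpression(
            m.span(), m.group(0), ExpressionKind.CLOCK_AMPM, hour=int(m.group("h"))
        )

    def b_mil_cue(m):
        tok = m.group("t")
        return TimeExpression(
            m.span("t"), tok, ExpressionKind.MILITARY,
            hour=int(tok[:2]), minute=int(tok[2:]),
        )

    families = [
        (_P_RANGE_OFFSET, b_range_offset),
        (_P_RANGE_CLOCK, b_range_clock),
        (_P_COMPOUND_RC, b_compound),
        (_P_COMPOUND_CR, b_compound),
        (_P_CLOCK12, b_clock12),
        (_P_HHMM, b_hhmm),
        # explicit military time after a temporal cue ("since 0530") —
        # the candidate span is the time token, so compounds like
        # "since 0530 today" still win as the longer match
        (_P_MIL_CUE, b_mil_cue, lambda m: m.span("t")),
        (_P_OFFSET, b_offset),
        (_P_WAKE, b_wake),
        (_P_DAYPART, b_daypart),
        (_P_REL, b_rel),
        (_P_PDATE, b_pdate),
        (_P_MONTHNAME, b_monthname),
    ]
    if not guard_distractors:
        families.append((_P_BARE, b_bare))
    exprs = _scan(text, families)
    if guard_distractors:
        exprs = [
            e for e in exprs
            if not (
                e.kind is ExpressionKind.CLOCK_AMPM
                and e.meridiem is None
                and e.minute in (None, 0)
                and e.raw.isdigit()
                and _followed_by_unit(text, e.span[1])
            )
        ]
    for e in exprs:
        e.check_against(text)
    return exprs


def correct_time_punctuation(token: str) -> str:
    """Correct a ``.`` used as the time separator, e.g. ``4.45 am`` -> ``4:45 am``.

    Only tokens shaped like a time — one or two digit hour, two-digit
    minutes 00–59 — are corrected; dosage-style decimals ("4.5 mg") are
    left untouched.
    """
    if re.search(r"\d\.\d+\s*[a-z/%]", token, re.IGNORECASE) and not re.search(
        rf"\d\.[0-5]\d\s*{_AMPM}", token, re.IGNORECASE
    ):
        return token
    return re.sub(
        r"(?<![\d:.])(\d{1,2})\.([0-5]\d)(?!\d)", r"\1:\2", token
    )


def parse_fallback(
    text: str, note_dt: Optional[datetime] = None
) -> List[TimeExpression]:
    """Scan for explicit numeric time mentions, in document order.

    Applies punctuation correction to dotted times, recognizes 12-hour,
    colon-separated and military times, and picks up a bare hour after a
    temporal cue word ("pain since 7"); meridiem inference for such
    expressions happens during anchoring.
    """

    def b_dottime(m):
        if m.group("mer") is None and _followed_by_unit(text, m.end()):
            return None
        mer = None
        if m.group("mer"):
            mer = Meridiem.PM if "p" in m.group("mer").lower() else Meridiem.AM
        kind = ExpressionKind.CLOCK_AMPM if mer else ExpressionKind.CLOCK_HHMM
        return TimeExpression(
            m.span(), m.group(0), kind,
            hour=int(m.group("h")), minute=int(m.group("m")), meridiem=mer,
        )

    def b_clock12(m):
        mer = Meridiem.PM if m.group("mer").lower().startswith("p") else Meridiem.AM
        return TimeExpression(
            m.span(), m.group(0), ExpressionKind.CLOCK_AMPM,
            hour=int(m.group("h")), minute=int(m.group("m") or 0), meridiem=mer,
        )

    def b_hhmm(m):
        hh, mm = m.group("t").split(":")
        return TimeExpression(
            m.span(), m.group(0), ExpressionKind.CLOCK_HHMM,
            hour=int(hh), minute=int(mm),
        )

    def b_mil(m):
        tok = m.group("t")
        if 1900 <= int(tok) <= 2099 and not re.search(
            rf"{_cue}\s*$", text[max(0, m.start() - 12):m.start()], re.IGNORECASE
        ):
            logger.info("skipping year-like token %r without a time cue", tok)
            return None
        return TimeExpression(
            m.span(), m.group(0), ExpressionKind.MILITARY,
            hour=int(tok[:2]), minute=int(tok[2:]),
        )

    def b_bare_cue(m):
        start, end = m.span("h")
        if _followed_by_unit(text, end):
            return None
        return TimeExpression(
            (start, end), m.group("h"), ExpressionKind.CLOCK_AMPM,
            hour=int(m.group("h")),
        )

    exprs = _scan(text, [
        (_P_DOTTIME, b_dottime),
        (_P_CLOCK12, b_clock12),
        (_P_HHMM, b_hhmm),
        (_P_MIL, b_mil),
        (_P_BARE_CUE, b_bare_cue, lambda m: m.span("h")),
    ])
    for e in exprs:
        e.check_against(text)
    return exprs


# ---------------------------------------------------------------------------
# meridiem inference and anchoring

_AM_CUES = _c(r"\b(?:mid-?\s?morning|morning|dawn|sunrise|breakfast)\b")
_PM_CUES = _c(r"\b(?:afternoon|evening|night|tonight|dinner|supper|lunch|noon)\b")


def infer_meridiem(
    hour: int, minute: Optional[int], context: str, note_dt: datetime
) -> int:
    """Resolve a 12-hour value with missing am/pm into a 0–23 hour.

    A daypart word co-occurring in the surrounding context decides the half
    of day; otherwise the candidate (am or pm, today or the previous day)
    that anchors latest while staying at or before the note DateTime wins.
    Hours 13–23 are already unambiguous and pass through.
    """
    if hour > 12:
        return hour
    am_h = 0 if hour == 12 else hour
    pm_h = 12 if hour == 12 else hour + 12
    has_am = bool(_AM_CUES.search(context))
    has_pm = bool(_PM_CUES.search(context))
    if has_am and not has_pm:
        return am_h
    if has_pm and not has_am:
        return pm_h
    minute = minute or 0
    best = None
    for h in (am_h, pm_h):
        for back in (0, 1):
            cand = note_dt.replace(
                hour=h, minute=minute, second=0, microsecond=0
            ) - timedelta(days=back)
            if cand <= note_dt and (best is None or cand > best):
                best = cand
    return best.hour


_LITERAL_HHMM = _c(r"(?<![\d:])(0\d|1[3-9]|2[0-3]):[0-5]\d")


def _resolve_hour24(expr: TimeExpression, text: str, note_dt: datetime) -> int:
    if expr.meridiem is not None:
        return expr.hour % 12 + (12 if expr.meridiem is Meridiem.PM else 0)
    if expr.kind is ExpressionKind.MILITARY or expr.hour >= 13:
        return expr.hour
    if expr.kind is ExpressionKind.CLOCK_HHMM and _LITERAL_HHMM.search(expr.raw):
        return expr.hour  # leading-zero or 24-hour rendering: no inference
    start, end = expr.span
    context = text[max(0, start - 60):min(len(text), end + 60)]
    return infer_meridiem(expr.hour, expr.minute, context, note_dt)


def _anchor_with_rel(
    hour: int, minute: int, rel: str, note_dt: datetime
) -> datetime:
    day0 = note_dt.replace(hour=hour, minute=minute, second=0, microsecond=0)
    if rel in ("yesterday", "yesterday morning", "yesterday evening", "last evening"):
        return day0 - timedelta(days=1)
    if rel == "last night":
        # pm times belong to the previous evening; small-hour am times may
        # be the early hours of the note's own day
        if hour >= 12 or day0 > note_dt:
            return day0 - timedelta(days=1)
        return day0
    if rel == "next week":
        return day0 + timedelta(days=7)
    # today / this morning / this afternoon / this evening / tonight
    if day0 > note_dt:
        logger.warning(
            "clock time %02d:%02d 'today' falls after the note DateTime; "
            "anchoring to the previous day (onset precedes presentation)",
            hour, minute,
        )
        return day0 - timedelta(days=1)
    return day0


_REL_ALONE_DAYPART = {
    "this morning": "morning",
    "yesterday morning": "morning",
    "this afternoon": "afternoon",
    "this evening": "evening",
    "yesterday evening": "evening",
    "tonight": "evening",
}


def anchor_expression(
    expr: TimeExpression,
    text: str,
    note_dt: datetime,
    stage: Stage = Stage.PRIMARY,
) -> Optional[NormalizedOnset]:
    """Anchor a detected expression to an absolute onset DateTime.

    Returns ``None`` for expressions with no resolvable DateTime (e.g. a
    standalone year).  Clock times without an explicit date use the note's
    day, or the previous day when the time would fall after the note.
    """
    kind = expr.kind
    if kind in (
        ExpressionKind.CLOCK_AMPM,
        ExpressionKind.CLOCK_HHMM,
        ExpressionKind.MILITARY,
    ):
        hour = _resolve_hour24(expr, text, note_dt)
        minute = expr.minute or 0
        if expr.rel_word is None:
            onset = rules.anchor_clock(hour, minute, note_dt)
        else:
            onset = _anchor_with_rel(hour, minute, expr.rel_word, note_dt)
        return NormalizedOnset(expr, onset, stage)
    if kind in (ExpressionKind.DAYPART, ExpressionKind.WAKE_PHRASE):
        t = rules.lookup_daypart(expr.raw)
        if t is None:
            return None
        onset = rules.anchor_clock(t.hour, t.minute, note_dt)
        return NormalizedOnset(expr, onset, Stage.LEXICON)
    if kind is ExpressionKind.RELATIVE_OFFSET:
        onset = rules.resolve_relative_offset(
            expr.offset_quantity, expr.offset_unit, note_dt
        )
        return NormalizedOnset(expr, onset, stage)
    if kind is ExpressionKind.RELATIVE_WORD:
        rel = expr.rel_word
        if rel == "today":
            return NormalizedOnset(expr, note_dt, stage)
        if rel == "yesterday":
            return NormalizedOnset(expr, note_dt - timedelta(days=1), stage)
        if rel in ("last night", "last evening", "yesterday evening"):
            t = rules.lookup_daypart("evening")
            onset = (note_dt - timedelta(days=1)).replace(
                hour=t.hour, minute=t.minute, second=0, microsecond=0
            )
            return NormalizedOnset(expr, onset, Stage.LEXICON)
        if rel in _REL_ALONE_DAYPART:
            t = rules.lookup_daypart(_REL_ALONE_DAYPART[rel])
            if rel.startswith("yesterday"):
                onset = (note_dt - timedelta(days=1)).replace(
                    hour=t.hour, minute=t.minute, second=0, microsecond=0
                )
            else:
                onset = rules.anchor_clock(t.hour, t.minute, note_dt)
            return NormalizedOnset(expr, onset, Stage.LEXICON)
        if rel == "next week":
            return NormalizedOnset(expr, note_dt + timedelta(days=7), stage)
        return None
    if kind is ExpressionKind.RANGE:
        try:
            chosen = rules.resolve_range(*expr.endpoints, note_dt)
        except rules.FlaggedResultError:
            logger.warning("range %r has no endpoint before the note DateTime", expr.raw)
            return None
        onset = rules.anchor_endpoint(chosen, note_dt)
        return NormalizedOnset(expr, onset, stage)
    if kind is ExpressionKind.PARTIAL_DATE:
        if expr.month is None or expr.day is None:
            return None
        year = expr.year
        try:
            if year is None:
                year = note_dt.year
                if datetime(year, expr.month, expr.day) > note_dt:
                    year -= 1  # onset precedes presentation
            onset = datetime(year, expr.month, expr.day)
        except ValueError:
            return None
        return NormalizedOnset(expr, onset, stage)
    return None  # YEAR and anything unresolvable


@dataclass
class ExtractionResult:
    """Anchored outputs for one note, in document order of their spans."""

    note_id: str
    outputs: List[NormalizedOnset]
    n_outputs: int
    mode: Mode
    note_type: Optional[NoteType] = None
    resolved: Optional[NormalizedOnset] = None

    def __post_init__(self) -> None:
        if self.n_outputs != len(self.outputs):
            raise ValueError("n_outputs must equal len(outputs)")


def extract_onsets(
    note: ClinicalNote, mode: Mode = "extended", *, run_both: bool = False
) -> ExtractionResult:
    """Run the hybrid pipeline on one note.

    The primary scanner runs first; the fallback explicit-time scanner runs
    only when the primary finds nothing (or always, with ``run_both``).
    Faithful mode emits every anchored output, duplicates included.
    Extended mode drops anchors after the note DateTime, deduplicates
    identical canonical strings, and resolves the remaining candidates with
    the most-recent-episode rule into ``resolved``.
    """
    if mode not in ("faithful", "extended"):
        raise ValueError(f"unknown mode {mode!r}")
    guard = mode == "extended"
    note_dt = note.note_datetime
    staged = [(e, Stage.PRIMARY) for e in
              parse_primary(note.text, note_dt, guard_distractors=guard)]
    if not staged or run_both:
        staged += [(e, Stage.FALLBACK) for e in parse_fallback(note.text, note_dt)]
    staged.sort(key=lambda pair: pair[0].span)

    outputs: List[NormalizedOnset] = []
    for expr, stage in staged:
        onset = anchor_expression(expr, note.text, note_dt, stage)
        if onset is None:
            continue
        if mode == "extended" and onset.onset > note_dt:
            logger.info("dropping future anchor %s in extended mode", onset.formatted)
            continue
        outputs.append(onset)

    resolved = None
    if mode == "extended":
        seen = set()
        deduped = []
        for o in outputs:
            if o.formatted not in seen:
                seen.add(o.formatted)
                deduped.append(o)
        outputs = deduped
        if outputs:
            # explicit clock/offset onsets outrank lexicon-default guesses:
            # a daypart word alongside an explicit time is usually the same
            # episode restated, not a separate, later episode
            explicit = [o for o in outputs if o.stage is not Stage.LEXICON]
            pool = explicit or outputs
            best = rules.select_most_recent([o.onset for o in pool], note_dt)
            resolved = next(o for o in pool if o.onset == best)

    return ExtractionResult(
        note_id=note.note_id,
        outputs=outputs,
        n_outputs=len(outputs),
        mode=mode,
        note_type=note.note_type,
        resolved=resolved,
    )
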