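"""Pattern-matching extraction pipeline.

A suite of six case-insensitive regular-expression families detects
temporal expressions and labels each with a format category for
tabulation:

1. colon-separated 24-hour times ("20:30"),
2. 12-hour times with am/pm ("11:30 am", "3am"),
3. 4-digit military times ("0530"),
4. clock time + relative word combinations ("0530 today", "9 pm last night"),
5. month-name and numeric dates ("Mar 2, 2016", "03/20"), and
6. standalone relative words and 4-digit years.

Matches never overlap: the longest match at each position wins, with
family precedence 4 > 1 > 2 > 3 > 5 > 6 breaking ties, so "0530 today" is
one combined expression rather than a military time plus a relative word.

By design the faithful anchoring mode returns no canonical-format
outputs: the pattern pipeline stops at labeled expressions.  The extended
mode reuses the hybrid pipeline's anchoring machinery.
"""

from __future__ import annotations

import logging
import re
from datetime import datetime
from typing import List, Optional

from . import hybrid
from .types import (
    ExpressionKind,
    FormatCategory,
    Meridiem,
    NormalizedOnset,
    Stage,
    TimeExpression,
)

logger = logging.getLogger(__name__)

_AMPM = r"[ap]\.?m\.?(?![a-z0-9])"
_T_HHMM = r"(?<![\d:.])(?:[01]?\d|2[0-3]):[0-5]\d(?![\d:])"
_T_CLOCK12 = rf"(?:1[0-2]|0?[1-9])(?::[0-5]\d)?\s*{_AMPM}"
_T_MIL = r"(?<![\d:/.])(?:[01]\d|2[0-3])[0-5]\d(?![\d:/])"
_T_CLOCKANY = rf"(?:{_T_CLOCK12}|{_T_HHMM}|{_T_MIL})"
_T_REL = (
    r"(?:last\s+night|last\s+evening|this\s+morning|this\s+evening|"
    r"this\s+afternoon|tonight|today|yesterday)"
)
_T_MONTH = (
    r"(?:jan(?:uary)?|feb(?:ruary)?|mar(?:ch)?|apr(?:il)?|may|jun(?:e)?|"
    r"jul(?:y)?|aug(?:ust)?|sep(?:t|tember)?|oct(?:ober)?|nov(?:ember)?|"
    r"dec(?:ember)?)"
)

_FAMILIES = [
    # (family number, compiled pattern); listed in precedence order
    (4, re.compile(
        rf"(?:{_T_CLOCKANY}\s+{_T_REL}\b|\b{_T_REL}\s+(?:at\s+)?{_T_CLOCKANY})",
        re.IGNORECASE,
    )),
    (1, re.compile(rf"{_T_HHMM}(?!\s*{_AMPM})", re.IGNORECASE)),
    (2, re.compile(rf"\b{_T_CLOCK12}", re.IGNORECASE)),
    (3, re.compile(_T_MIL, re.IGNORECASE)),
    (5, re.compile(
        rf"(?:\b(?:on|at)\s+)?(?:\b{_T_MONTH}\.?\s+\d{{1,2}}(?:,?\s+\d{{4}})?\b"
        r"|(?<![\d/.])(?:0?[1-9]|1[0-2])/(?:0?[1-9]|[12]\d|3[01])(?:/\d{2,4})?(?![\d/]))",
        re.IGNORECASE,
    )),
    (6, re.compile(
        rf"(?:\b{_T_REL}\b|\b(?:morning|afternoon|evening|noon|midnight)\b"
        r"|(?<![\d:/.])(?:19|20)\d\d(?![\d:/]))",
        re.IGNORECASE,
    )),
]

_TIME_CUE_BEFORE = re.compile(
    r"(?:since|at|around|about|until|till|approx\w*\.?|@|by)\s*$", re.IGNORECASE
)


def _classify_match(family: int, raw: str, text: str, start: int) -> Optional[TimeExpression]:
    low = raw.lower()
    if family == 4:
        rel_m = re.search(rf"\b{_T_REL}\b", low)
        clock_raw = (low[:rel_m.start()] + low[rel_m.end():]).strip(" ,")
        clock_raw = re.sub(r"^(?:at|around)\s+", "", clock_raw).strip()
        skel = hybrid._parse_clock_token(clock_raw)
        return TimeExpression(
            (start, start + len(raw)), raw, skel.kind,
            hour=skel.hour, minute=skel.minute, meridiem=skel.meridiem,
            rel_word=re.sub(r"\s+", " ", rel_m.group(0)),
        )
    span = (start, start + len(raw))
    if family == 1:
        hh, mm = low.split(":")
        return TimeExpression(span, raw, ExpressionKind.CLOCK_HHMM,
                              hour=int(hh), minute=int(mm))
    if family == 2:
        m = re.match(r"(\d{1,2})(?::(\d{2}))?\s*([ap])", low)
        return TimeExpression(
            span, raw, ExpressionKind.CLOCK_AMPM,
            hour=int(m.group(1)), minute=int(m.group(2) or 0),
            meridiem=Meridiem.PM if m.group(3) == "p" else Meridiem.AM,
        )
    if family == 3:
        value = int(low)
        if 1900 <= value <= 2099 and not _TIME_CUE_BEFORE.search(
            text[max(0, start - 12):start]
        ):
            # ambiguous 4-digit token: plausible military time and plausible
            # year; without a time cue the year reading wins (family 6)
            logger.info("ambiguous 4-digit token %r read as a year", raw)
            return TimeExpression(span, raw, ExpressionKind.YEAR, year=value)
        return TimeExpression(span, raw, ExpressionKind.MILITARY,
                              hour=int(low[:2]), minute=int(low[2:]))
    if family == 5:
        body = re.sub(r"^(?:on|at)\s+", "", low).strip()
        month = day = year = None
        m = re.match(r"(\d{1,2})/(\d{1,2})(?:/(\d{2,4}))?$", body)
        if m:
            month, day = int(m.group(1)), int(m.group(2))
            if m.group(3):
                year = int(m.group(3))
                year += 2000 if year < 70 else (1900 if year < 100 else 0)
        else:
            m = re.match(rf"({_T_MONTH})\.?\s+(\d{{1,2}})(?:,?\s+(\d{{4}}))?$", body)
            if m:
                month = hybrid._MONTHS[m.group(1)[:3]]
                day = int(m.group(2))
                year = int(m.group(3)) if m.group(3) else None
        return TimeExpression(span, raw, ExpressionKind.PARTIAL_DATE,
                              month=month, day=day, year=year)
    # family 6
    if re.fullmatch(r"(?:19|20)\d\d", low):
        return TimeExpression(span, raw, ExpressionKind.YEAR, year=int(low))
    return TimeExpression(span, raw, ExpressionKind.RELATIVE_WORD,
                          rel_word=re.sub(r"\s+", " ", low))


def extract_expressions_regex(text: str) -> List[TimeExpression]:
    """Apply the six pattern families and return non-overlapping matches.

    Matches come back in document order, each labeled with a format
    category; precedence is deterministic (longest match, then family
    order), so repeated runs on the same text are identical.
    """
    candidates = []
    for prio, (family, pattern) in enumerate(_FAMILIES):
        for m in pattern.finditer(text):
            candidates.append((m.start(), m.end(), prio, family, m.group(0)))
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0]), c[2]))
    chosen: List[TimeExpression] = []
    occupied_until = -1
    for start, end, _, family, raw in candidates:
        if start < occupied_until:
            continue
        expr = _classify_match(family, raw, text, start)
        if expr is None:
            continue
        expr.check_against(text)
        chosen.append(expr)
        occupied_until = end
    return chosen


def categorize_format(expr: TimeExpression) -> FormatCategory:
    """Format-category label of an extracted expression.

    Exactly one of HHMM_COLON, HH_AMPM, MILITARY, HOUR_PLUS_RELATIVE,
    YYYY, OTHER; deterministic under the family precedence order.
    """
    return expr.format_category


def anchor_regex_outputs(
    exprs: List[TimeExpression],
    note_dt: datetime,
    mode: hybrid.Mode = "faithful",
    text: str = "",
) -> List[NormalizedOnset]:
    """Anchor pattern-suite expressions to absolute onset DateTimes.

    Faithful mode returns an empty list for any input: the pattern
    pipeline, as built, never emits canonical ``MM/DD/YYYY HH:MM`` outputs.
    Extended mode anchors each expression with the shared rule machinery
    and drops anchors after the note DateTime.
    """
    if mode == "faithful":
        return []
    outputs = []
    for expr in exprs:
        onset = hybrid.anchor_expression(expr, text, note_dt, Stage.PRIMARY)
        if onset is None or onset.onset > note_dt:
            continue
        outputs.append(onset)
    return outputs
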