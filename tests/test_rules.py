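from datetime import datetime, time, timedelta

import pytest
from hypothesis import given
from hypothesis import strategies as st

from onsetdt.rules import (
    LEXICON,
    FlaggedResultError,
    OffsetRangeError,
    RuleSource,
    lookup_daypart,
    resolve_range,
    resolve_relative_offset,
    select_most_recent,
)
from onsetdt.types import ExpressionKind, TimeExpression

# the full daypart rule table, asserted literally
EXPECTED_LEXICON = {
    "morning": (time(7, 0), RuleSource.AHA),
    "lunch time": (time(12, 0), RuleSource.AHA),
    "afternoon": (time(15, 0), RuleSource.AHA),
    "dinner time": (time(18, 0), RuleSource.AHA),
    "evening": (time(22, 0), RuleSource.AHA),
    "awaken from sleep": (time(3, 0), RuleSource.AHA),
    "midmorning": (time(9, 0), RuleSource.EXTENDED),
    "wake up in the morning": (time(6, 0), RuleSource.EXTENDED),
    "after lunch": (time(13, 0), RuleSource.EXTENDED),
    "after dinner": (time(19, 0), RuleSource.EXTENDED),
}


def test_lexicon_contains_every_rule_exactly_once():
    assert {e.phrase: (e.clock_time, e.source) for e in LEXICON} == EXPECTED_LEXICON
    assert len(LEXICON) == len(EXPECTED_LEXICON)


@pytest.mark.parametrize(
    "phrase, expected",
    [
        ("morning", time(7, 0)),
        ("midmorning", time(9, 0)),
        ("AWAKEN FROM SLEEP", time(3, 0)),   # case-insensitive
        ("he woke", time(3, 0)),             # wake-verb variant, pronoun stripped
        ("woke up", time(3, 0)),
        ("woke up this morning", time(6, 0)),  # wake adjacent to morning
        ("lunchtime", time(12, 0)),
        ("this evening", time(22, 0)),
        ("while driving", None),
        ("", None),
    ],
)
def test_lookup_daypart(phrase, expected):
    assert lookup_daypart(phrase) == expected


def test_one_day_ago_worked_example():
    note_dt = datetime(2000, 1, 1, 8, 35)
    assert resolve_relative_offset(1, "day", note_dt) == datetime(1999, 12, 31, 8, 35)


def test_offset_identity_and_hours_across_midnight():
    x = datetime(2000, 6, 15, 12, 30)
    assert resolve_relative_offset(0, "day", x) == x
    assert resolve_relative_offset(4, "hour", datetime(2000, 1, 1, 2, 0)) == datetime(
        1999, 12, 31, 22, 0
    )


def test_weeks_equal_stepping_back_single_days():
    note_dt = datetime(2000, 1, 22, 10, 0)
    oracle = note_dt
    for _ in range(21):
        oracle -= timedelta(days=1)
    assert resolve_relative_offset(3, "week", note_dt) == oracle
    assert oracle == datetime(2000, 1, 1, 10, 0)


@given(
    st.datetimes(min_value=datetime(1950, 1, 1), max_value=datetime(2099, 1, 1)),
    st.integers(min_value=0, max_value=60),
)
def test_day_offsets_match_single_day_stepping_oracle(anchor, days):
    """Day offsets preserve the clock time and equal one-day-at-a-time stepping."""
    anchor = anchor.replace(second=0, microsecond=0)
    oracle = anchor
    for _ in range(days):
        oracle -= timedelta(days=1)
    got = resolve_relative_offset(days, "day", anchor)
    assert got == oracle
    assert (got.hour, got.minute) == (anchor.hour, anchor.minute)


def test_offset_before_supported_range_raises():
    with pytest.raises(OffsetRangeError):
        resolve_relative_offset(200, "week", datetime(1901, 1, 1, 0, 0))


def test_month_offsets_clamp_day_of_month():
    # 3/31 minus one calendar month clamps to 2/28 (or 2/29 in leap years)
    assert resolve_relative_offset(1, "month", datetime(2001, 3, 31, 9, 0)) == datetime(
        2001, 2, 28, 9, 0
    )


def _mil(raw, hour, minute=0):
    return TimeExpression((0, len(raw)), raw, ExpressionKind.MILITARY,
                          hour=hour, minute=minute)


def _ago(q, unit="day"):
    raw = f"{q} {unit}s ago"
    return TimeExpression((0, len(raw)), raw, ExpressionKind.RELATIVE_OFFSET,
                          offset_quantity=q, offset_unit=unit)


def test_clock_range_uses_later_value():
    note_dt = datetime(2000, 1, 1, 8, 35)
    chosen = resolve_range(_mil("0200", 2), _mil("0300", 3), note_dt)
    assert chosen.raw == "0300"


def test_ago_range_uses_smaller_offset():
    note_dt = datetime(2000, 1, 10, 8, 0)
    assert resolve_range(_ago(2), _ago(3), note_dt).raw == "2 days ago"
    assert resolve_range(_ago(3, "week"), _ago(5, "week"), note_dt).raw == "3 weeks ago"


def test_equal_range_endpoints():
    note_dt = datetime(2000, 1, 1, 8, 35)
    assert resolve_range(_mil("0300", 3), _mil("0300", 3), note_dt).raw == "0300"


@given(
    st.datetimes(min_value=datetime(1990, 1, 1), max_value=datetime(2050, 1, 1)),
    st.integers(min_value=0, max_value=23), st.integers(min_value=0, max_value=59),
    st.integers(min_value=0, max_value=23), st.integers(min_value=0, max_value=59),
)
def test_range_resolution_never_anchors_after_note(note_dt, h1, m1, h2, m2):
    from onsetdt.rules import anchor_endpoint

    note_dt = note_dt.replace(second=0, microsecond=0)
    a = _mil(f"{h1:02d}{m1:02d}", h1, m1)
    b = _mil(f"{h2:02d}{m2:02d}", h2, m2)
    chosen = resolve_range(a, b, note_dt)
    assert anchor_endpoint(chosen, note_dt) <= note_dt


def test_most_recent_episode_prior_to_presentation():
    note_dt = datetime(1999, 12, 31, 8, 0)
    candidates = [datetime(1999, 12, 30, 21, 0), datetime(1999, 12, 31, 3, 0)]
    assert select_most_recent(candidates, note_dt) == datetime(1999, 12, 31, 3, 0)
    assert select_most_recent([candidates[0]], note_dt) == candidates[0]


def test_most_recent_all_future_is_flagged():
    note_dt = datetime(2000, 1, 1, 0, 0)
    with pytest.raises(FlaggedResultError):
        select_most_recent([datetime(2000, 1, 2, 0, 0)], note_dt)


@given(
    st.lists(
        st.datetimes(min_value=datetime(1990, 1, 1), max_value=datetime(2010, 1, 1)),
        min_size=1, max_size=50,
    ),
    st.datetimes(min_value=datetime(1990, 1, 1), max_value=datetime(2010, 1, 1)),
)
def test_most_recent_matches_brute_force_filter(candidates, note_dt):
    eligible = [c for c in candidates if c <= note_dt]
    if not eligible:
        with pytest.raises(FlaggedResultError):
            select_most_recent(candidates, note_dt)
    else:
        assert select_most_recent(candidates, note_dt) == max(eligible)
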