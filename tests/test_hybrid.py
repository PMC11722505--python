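from datetime import datetime, timedelta

import pytest
from hypothesis import given
from hypothesis import strategies as st

from onsetdt.hybrid import (
    correct_time_punctuation,
    extract_onsets,
    infer_meridiem,
    parse_fallback,
    parse_primary,
)
from onsetdt.types import ExpressionKind, Meridiem

SENT_LAST_NIGHT = (
    "c/o cp which began last night at 9 pm while he was watching TV, denies "
    "being diaphoretic or nausea. has taken 6 nitro since last night. "
    "has had 6 stents in past. ekg in triage"
)
SENT_WOKE = (
    "He was in his usual state of health until approx 3AM today, when he "
    "says he woke and had severe chest discomfort/pressure"
)
SENT_DOTTED = (
    "66 y/o male presents to SMH ED with complains of chest pain since "
    "morning 4.45 am"
)


class TestParsePrimary:
    def test_detects_compound_relative_plus_clock(self):
        exprs = parse_primary(SENT_LAST_NIGHT)
        assert exprs[0].raw == "last night at 9 pm"
        assert exprs[0].kind is ExpressionKind.CLOCK_AMPM
        assert (exprs[0].hour, exprs[0].meridiem) == (9, Meridiem.PM)
        assert exprs[0].rel_word == "last night"

    def test_distractor_numerals_guarded_in_extended_mode(self):
        raws = [e.raw for e in parse_primary(SENT_LAST_NIGHT)]
        assert raws == ["last night at 9 pm", "last night"]
        assert "6" not in raws

    def test_unguarded_scan_misreads_distractor_numerals(self):
        # the classic failure of generic parsers on doses/counts
        raws = [e.raw for e in parse_primary(SENT_LAST_NIGHT, guard_distractors=False)]
        assert raws.count("6") == 2

    def test_clock_and_wake_phrase_both_detected(self):
        exprs = parse_primary(SENT_WOKE)
        assert [(e.raw, e.kind) for e in exprs] == [
            ("3AM today", ExpressionKind.CLOCK_AMPM),
            ("he woke", ExpressionKind.WAKE_PHRASE),
        ]

    def test_empty_text(self):
        assert parse_primary("") == []

    def test_spans_recover_raw_and_are_ordered(self):
        text = "pain 2 days ago, again yesterday at 14:30, took 5 mg asa"
        exprs = parse_primary(text)
        for e in exprs:
            e.check_against(text)
        starts = [e.span[0] for e in exprs]
        assert starts == sorted(starts)

    @pytest.mark.parametrize(
        "text, kind, fields",
        [
            ("began four hours ago", ExpressionKind.RELATIVE_OFFSET,
             {"offset_quantity": 4, "offset_unit": "hour"}),
            ("started 2 days ago", ExpressionKind.RELATIVE_OFFSET,
             {"offset_quantity": 2, "offset_unit": "day"}),
            ("cp since 03/20", ExpressionKind.PARTIAL_DATE,
             {"month": 3, "day": 20}),
            ("cp since Mar 2, 2016", ExpressionKind.PARTIAL_DATE,
             {"month": 3, "day": 2, "year": 2016}),
            ("hurts since yesterday", ExpressionKind.RELATIVE_WORD,
             {"rel_word": "yesterday"}),
            ("worse since midmorning", ExpressionKind.DAYPART, {}),
        ],
    )
    def test_expression_families(self, text, kind, fields):
        exprs = parse_primary(text)
        assert len(exprs) == 1, exprs
        assert exprs[0].kind is kind
        for name, value in fields.items():
            got = getattr(exprs[0], name)
            got = got.value if hasattr(got, "value") else got
            assert got == value

    def test_range_expression_has_two_endpoints(self):
        (expr,) = parse_primary("pain began around 0200-0300 this am")
        assert expr.kind is ExpressionKind.RANGE
        assert [e.raw for e in expr.endpoints] == ["0200", "0300"]


class TestParseFallback:
    def test_captures_dotted_time_with_meridiem(self):
        exprs = parse_fallback(SENT_DOTTED)
        assert [(e.raw, e.hour, e.minute, e.meridiem) for e in exprs] == [
            ("4.45 am", 4, 45, Meridiem.AM)
        ]

    def test_no_temporal_content(self):
        assert parse_fallback("no temporal content here") == []

    def test_bare_hour_after_cue(self):
        (expr,) = parse_fallback("pain since 7 this evening per family")
        assert (expr.raw, expr.hour, expr.meridiem) == ("7", 7, None)

    def test_dotted_dose_not_a_time(self):
        assert parse_fallback("gave 6.50 mg morphine") == []


@pytest.mark.parametrize(
    "token, expected",
    [
        ("4.45 am", "4:45 am"),
        ("4:45 am", "4:45 am"),
        ("4.5 mg", "4.5 mg"),
        ("12.30", "12:30"),
    ],
)
def test_correct_time_punctuation(token, expected):
    assert correct_time_punctuation(token) == expected


class TestInferMeridiem:
    def test_daypart_context_decides(self):
        note_dt = datetime(2000, 1, 5, 10, 0)
        assert infer_meridiem(4, 45, "since morning", note_dt) == 4
        assert infer_meridiem(7, 0, "pain this evening", note_dt) == 19

    def test_hour_over_twelve_passes_through(self):
        assert infer_meridiem(13, 0, "", datetime(2000, 1, 1, 14, 0)) == 13

    def test_no_cues_latest_candidate_not_after_note(self):
        # note at 01/02 06:00; candidates 07:00/19:00 today or yesterday;
        # latest not-after is yesterday 19:00
        assert infer_meridiem(7, 0, "", datetime(2000, 1, 2, 6, 0)) == 19

    @given(
        st.integers(min_value=1, max_value=12),
        st.datetimes(min_value=datetime(2000, 1, 2), max_value=datetime(2001, 1, 1)),
    )
    def test_matches_brute_force_over_four_candidates(self, hour, note_dt):
        note_dt = note_dt.replace(second=0, microsecond=0)
        got = infer_meridiem(hour, 0, "", note_dt)
        candidates = []
        for h in {hour % 12, hour % 12 + 12} if hour != 12 else {0, 12}:
            for back in (0, 1):
                c = note_dt.replace(hour=h, minute=0) - timedelta(days=back)
                if c <= note_dt:
                    candidates.append(c)
        assert got == max(candidates).hour


class TestExtractOnsets:
    def test_faithful_mode_returns_two_identical_outputs(self, make_note):
        note = make_note(SENT_WOKE, datetime(2000, 1, 5, 10, 15))
        result = extract_onsets(note, "faithful")
        assert result.n_outputs == 2
        assert result.outputs[0].formatted == result.outputs[1].formatted
        assert result.outputs[0].formatted == "01/05/2000 03:00"

    def test_extended_mode_deduplicates_and_resolves(self, make_note):
        note = make_note(SENT_WOKE, datetime(2000, 1, 5, 10, 15))
        result = extract_onsets(note, "extended")
        assert result.n_outputs == 1
        assert result.resolved.formatted == "01/05/2000 03:00"

    def test_empty_note_yields_zero_outputs(self, make_note):
        result = extract_onsets(make_note(""), "faithful")
        assert result.n_outputs == 0 and result.outputs == []

    def test_last_night_at_9pm_anchors_to_previous_evening(self, make_note):
        note = make_note(SENT_LAST_NIGHT, datetime(2000, 1, 6, 10, 0))
        result = extract_onsets(note, "extended")
        assert result.resolved.formatted == "01/05/2000 21:00"

    def test_fallback_runs_only_when_primary_is_empty(self, make_note):
        # dotted time is fallback-only, but 'morning' satisfies the primary
        note = make_note(SENT_DOTTED, datetime(2000, 1, 5, 10, 0))
        stages = {o.stage.value for o in extract_onsets(note, "extended").outputs}
        assert "fallback" not in stages
        note2 = make_note("cp started 4.45 am", datetime(2000, 1, 5, 10, 0))
        result2 = extract_onsets(note2, "extended")
        assert result2.resolved.formatted == "01/05/2000 04:45"
        assert result2.outputs[0].stage.value == "fallback"

    def test_run_both_adds_fallback_expressions(self, make_note):
        note = make_note(SENT_DOTTED, datetime(2000, 1, 5, 10, 0))
        result = extract_onsets(note, "extended", run_both=True)
        assert "04:45" in {o.onset.strftime("%H:%M") for o in result.outputs}

    def test_extended_resolved_never_after_note(self, make_note):
        note = make_note("follow up next week for stress test",
                         datetime(2000, 1, 5, 10, 0))
        result = extract_onsets(note, "extended")
        assert all(o.onset <= note.note_datetime for o in result.outputs)

    def test_partial_date_takes_note_year_or_previous(self, make_note):
        note = make_note("cp since 03/20", datetime(2000, 5, 1, 9, 0))
        assert extract_onsets(note, "extended").resolved.formatted == \
            "03/20/2000 00:00"
        early = make_note("cp since 03/20", datetime(2000, 2, 1, 9, 0))
        assert extract_onsets(early, "extended").resolved.formatted == \
            "03/20/1999 00:00"

    def test_daypart_rolls_to_previous_day_before_trigger_time(self, make_note):
        # note written at 05:00; "evening" (22:00) must mean yesterday evening
        note = make_note("cp since evening", datetime(2000, 1, 5, 5, 0))
        assert extract_onsets(note, "extended").resolved.formatted == \
            "01/04/2000 22:00"
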