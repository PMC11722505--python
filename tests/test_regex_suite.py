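from datetime import datetime

import pytest

from onsetdt.regexsuite import (
    anchor_regex_outputs,
    categorize_format,
    extract_expressions_regex,
)
from onsetdt.types import FormatCategory


def test_military_plus_relative_is_one_expression():
    text = "C/o midsternal chest pain radiating to right arm and neck since 0530 today"
    exprs = extract_expressions_regex(text)
    assert [(e.raw, e.format_category) for e in exprs] == [
        ("0530 today", FormatCategory.HOUR_PLUS_RELATIVE)
    ]


def test_no_temporal_content():
    assert extract_expressions_regex("no temporal content") == []


@pytest.mark.parametrize(
    "text, raw, category",
    [
        # colon-separated 24-hour times
        ("ekg done at 20:30", "20:30", FormatCategory.HHMM_COLON),
        ("pain at 01:30", "01:30", FormatCategory.HHMM_COLON),
        ("woke at 02:45 with cp", "02:45", FormatCategory.HHMM_COLON),
        # 12-hour with am/pm
        ("started around 10 pm", "10 pm", FormatCategory.HH_AMPM),
        ("cp since 11pm", "11pm", FormatCategory.HH_AMPM),
        ("since 3am per pt", "3am", FormatCategory.HH_AMPM),
        ("onset 11:30 am", "11:30 am", FormatCategory.HH_AMPM),
        # military
        ("pain since 0100", "0100", FormatCategory.MILITARY),
        ("onset 0630 per ems", "0630", FormatCategory.MILITARY),
        ("symptoms at 0045", "0045", FormatCategory.MILITARY),
        # clock + relative combinations
        ("cp 2200 yesterday", "2200 yesterday", FormatCategory.HOUR_PLUS_RELATIVE),
        ("began 11:30 pm last night", "11:30 pm last night",
         FormatCategory.HOUR_PLUS_RELATIVE),
        ("since 3am today", "3am today", FormatCategory.HOUR_PLUS_RELATIVE),
        ("cp 9 pm last night", "9 pm last night", FormatCategory.HOUR_PLUS_RELATIVE),
        ("onset 0315 today", "0315 today", FormatCategory.HOUR_PLUS_RELATIVE),
        # standalone years
        ("CABG in 2004", "2004", FormatCategory.YYYY),
        ("stent placed 2008", "2008", FormatCategory.YYYY),
        # dates and relative words tabulate as OTHER
        ("seen on Mar 2, 2016", "on Mar 2, 2016", FormatCategory.OTHER),
        ("cp since yesterday", "yesterday", FormatCategory.OTHER),
    ],
)
def test_expression_families_and_categories(text, raw, category):
    exprs = extract_expressions_regex(text)
    assert [e.raw for e in exprs] == [raw]
    assert categorize_format(exprs[0]) is category


def test_ambiguous_four_digit_token_with_time_cue_reads_as_time():
    (expr,) = extract_expressions_regex("pain began at 2004")
    assert expr.format_category is FormatCategory.MILITARY


def test_year_requires_bounds_and_digit_boundary():
    assert extract_expressions_regex("serial 21045 device") == []
    assert extract_expressions_regex("back in 1899") == []


def test_matches_never_overlap_and_are_deterministic():
    text = ("cp 9 pm last night, again 0530 today, hx CABG 2004, seen 03/20, "
            "ekg 20:30 and 11:30 am repeat")
    exprs = extract_expressions_regex(text)
    spans = [e.span for e in exprs]
    assert spans == sorted(spans)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2
    again = extract_expressions_regex(text)
    assert [(e.span, e.raw, e.format_category) for e in again] == [
        (e.span, e.raw, e.format_category) for e in exprs
    ]


def test_category_counts_are_exhaustive():
    text = "cp 9 pm last night, again 0530 today, hx CABG 2004, ekg 20:30"
    exprs = extract_expressions_regex(text)
    assert len(exprs) == sum(
        1 for e in exprs if e.format_category in FormatCategory
    )


class TestAnchoring:
    def test_faithful_mode_emits_no_canonical_outputs(self, make_note):
        texts = [
            "C/o midsternal chest pain radiating to right arm and neck since 0530 today",
            "ekg done at 20:30",
            "cp began last night at 9 pm",
            "",
        ]
        for text in texts:
            exprs = extract_expressions_regex(text)
            assert anchor_regex_outputs(
                exprs, datetime(2000, 1, 5, 9, 0), "faithful", text
            ) == []

    def test_extended_mode_anchors_against_note_datetime(self):
        text = "C/o midsternal chest pain radiating to right arm and neck since 0530 today"
        exprs = extract_expressions_regex(text)
        outputs = anchor_regex_outputs(exprs, datetime(2000, 1, 5, 9, 0),
                                       "extended", text)
        assert [o.formatted for o in outputs] == ["01/05/2000 05:30"]

    def test_empty_input_any_mode(self):
        for mode in ("faithful", "extended"):
            assert anchor_regex_outputs([], datetime(2000, 1, 5, 9, 0), mode) == []
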