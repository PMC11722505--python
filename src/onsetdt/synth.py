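"""Seeded generator of clinical-note-like sentences with gold onsets.

Protected clinical notes cannot ship with the package, so every pipeline
stage is exercised on synthetic triage/H&P-style sentences instead.  Each
generated note contains exactly one onset expression drawn from a template
family — 12-hour clock with am/pm, colon-separated 24-hour time, 4-digit
military time, daypart word, wake phrase, days/weeks-ago offset, time
range, or clock-plus-relative-word combination — rendered in clinical
register ("c/o", "cp", "pt") with optional distractor numerics (doses,
device counts) that a naive parser misreads as times.

The gold onset of every template is computed here by generator-side
calendar arithmetic that deliberately shares no code with the rule
module, so extractor-versus-gold agreement is a genuine cross-check.

What the generator does not emulate: full note length and section
structure, misspellings, and expressions outside the supported template
families.  Perfect recovery on this corpus therefore demonstrates
correctness of the parsing and anchoring rules, not performance on real
clinical text.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Dict, List, Tuple

import pandas as pd

from .types import ClinicalNote, NoteType, OnsetAnnotation

FAMILIES = (
    "clock_ampm",
    "hhmm_colon",
    "military",
    "daypart",
    "wake",
    "days_ago",
    "weeks_ago",
    "range",
    "hour_relative",
)

#: generator-side copy of the daypart rule times (independent of the rule
#: module on purpose — see module docstring)
_GOLD_DAYPART: Dict[str, Tuple[int, int]] = {
    "morning": (7, 0),
    "lunch time": (12, 0),
    "afternoon": (15, 0),
    "dinner time": (18, 0),
    "evening": (22, 0),
    "midmorning": (9, 0),
    "after lunch": (13, 0),
    "after dinner": (19, 0),
}

_GOLD_WAKE: Dict[str, Tuple[int, int]] = {
    "awoke from sleep": (3, 0),
    "woke up from sleep": (3, 0),
    "woke up": (3, 0),
    "woke up in the morning": (6, 0),
    "woke up this morning": (6, 0),
}

_PREAMBLES = (
    "{age} y/o {sex} presents to the ED with chest pain. ",
    "Pt is a {age} y/o {sex} c/o substernal cp. ",
    "{age} y/o {sex} with hx of htn presents c/o cp. ",
)

_FILLERS = (
    "denies sob or diaphoresis.",
    "pain described as pressure, non-radiating.",
    "ekg obtained in triage.",
    "states pain is ongoing.",
)

DISTRACTOR_TEMPLATES = (
    "has had {n} stents in past.",
    "has taken {n} nitro without relief.",
    "given {n} mg asa in triage.",
    "takes {n} tablets daily at home.",
)

_DISTRACTOR_RE = re.compile(
    r"\b\d+\s+(?:stents|nitro|mg asa|tablets)\b", re.IGNORECASE
)


def find_distractor_spans(text: str) -> List[Tuple[int, int]]:
    """Character spans of the distractor numerics inserted by the generator."""
    return [m.span() for m in _DISTRACTOR_RE.finditer(text)]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic corpus.

    Defaults mirror the pilot setting being emulated: a note-type mix of
    roughly 69% H&P, 27% Triage and 4% ED Screening (the 49/19/3 split of
    the 71-note study), uniform weight over the supported expression
    families, and distractor numerics in about a third of notes, which is
    how often dose/count figures appeared in the printed example sentences.
    """

    n_notes: int = 200
    seed: int = 0
    category_weights: Dict[str, float] = field(
        default_factory=lambda: {f: 1.0 / len(FAMILIES) for f in FAMILIES}
    )
    distractor_rate: float = 1.0 / 3.0
    note_type_mix: Dict[str, float] = field(
        default_factory=lambda: {"HP": 49 / 71, "TRIAGE": 19 / 71, "ED_SCREEN": 3 / 71}
    )
    note_datetime_window: Tuple[datetime, datetime] = (
        datetime(2024, 1, 1, 0, 0),
        datetime(2024, 12, 31, 23, 59),
    )
    multi_episode: bool = False

    def __post_init__(self) -> None:
        for name, weights in (
            ("category_weights", self.category_weights),
            ("note_type_mix", self.note_type_mix),
        ):
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"{name} has negative weights")
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} weights sum to {total}, expected 1")
        if not 0 <= self.distractor_rate <= 1:
            raise ValueError("distractor_rate must be a probability")
        unknown = set(self.category_weights) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown template families: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# generator-side gold arithmetic (independent oracle)

def _gold_clock(hour24: int, minute: int, note_dt: datetime) -> datetime:
    """Clock time on the note's day, stepped back a day if after the note."""
    cand = note_dt.replace(hour=hour24, minute=minute, second=0, microsecond=0)
    if cand > note_dt:
        cand -= timedelta(days=1)
    return cand


def _render_clock_ampm(rng: random.Random, note_dt: datetime):
    h = rng.randint(1, 12)
    minute = rng.choice((0, 15, 30, 45))
    pm = rng.random() < 0.5
    mer = ("pm" if pm else "am") if rng.random() < 0.7 else ("PM" if pm else "AM")
    tok = f"{h} {mer}" if minute == 0 else f"{h}:{minute:02d} {mer}"
    if minute == 0 and rng.random() < 0.3:
        tok = f"{h}{mer}"  # "3am" style, no space
    sentence = rng.choice(
        (f"c/o cp that began at {tok}.", f"chest pain started around {tok}.")
    )
    hour24 = (0 if h == 12 else h) + (12 if pm else 0)
    return sentence, _gold_clock(hour24, minute, note_dt)


def _render_hhmm_colon(rng: random.Random, note_dt: datetime):
    # hours 10-12 without a leading zero are ambiguous between 12- and
    # 24-hour readings, so this family sticks to unambiguous renderings
    hour = rng.choice((0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 13, 14, 15, 16, 17,
                       18, 19, 20, 21, 22, 23))
    minute = rng.randint(0, 59)
    sentence = f"chest pressure started at {hour:02d}:{minute:02d} per pt."
    return sentence, _gold_clock(hour, minute, note_dt)


def _render_military(rng: random.Random, note_dt: datetime):
    hour, minute = rng.randint(0, 23), rng.randint(0, 59)
    cue = rng.choice(("at", "since", "around"))
    sentence = f"c/o midsternal cp {cue} {hour:02d}{minute:02d}."
    return sentence, _gold_clock(hour, minute, note_dt)


def _render_daypart(rng: random.Random, note_dt: datetime):
    phrase = rng.choice(tuple(_GOLD_DAYPART))
    sentence = rng.choice(
        (f"c/o cp since {phrase}.", f"reports pain began around {phrase}.")
    )
    h, m = _GOLD_DAYPART[phrase]
    return sentence, _gold_clock(h, m, note_dt)


def _render_wake(rng: random.Random, note_dt: datetime):
    phrase = rng.choice(tuple(_GOLD_WAKE))
    sentence = f"pt {phrase} with crushing cp."
    h, m = _GOLD_WAKE[phrase]
    return sentence, _gold_clock(h, m, note_dt)


def _render_days_ago(rng: random.Random, note_dt: datetime):
    k = rng.randint(1, 6)
    unit = "day" if k == 1 else "days"
    sentence = f"symptoms started {k} {unit} ago."
    return sentence, note_dt - timedelta(days=k)


def _render_weeks_ago(rng: random.Random, note_dt: datetime):
    k = rng.randint(1, 5)
    unit = "week" if k == 1 else "weeks"
    sentence = f"cp began {k} {unit} ago."
    return sentence, note_dt - timedelta(days=7 * k)


def _render_range(rng: random.Random, note_dt: datetime):
    sep = rng.choice(("-", "–", " to "))
    subtype = rng.choice(("clock", "days", "weeks"))
    if subtype == "clock":
        t1 = rng.randint(0, 22 * 60)
        t2 = rng.randint(t1 + 1, min(t1 + 180, 23 * 60 + 59))
        a = f"{t1 // 60:02d}{t1 % 60:02d}"
        b = f"{t2 // 60:02d}{t2 % 60:02d}"
        sentence = f"chest pain or pressure began around {a}{sep}{b}."
        g1 = _gold_clock(t1 // 60, t1 % 60, note_dt)
        g2 = _gold_clock(t2 // 60, t2 % 60, note_dt)
        return sentence, max(g1, g2)  # closest to, not after, the note
    k1 = rng.randint(1, 4)
    k2 = rng.randint(k1 + 1, k1 + 3)
    unit = "days" if subtype == "days" else "weeks"
    sentence = f"reports cp starting {k1}{sep}{k2} {unit} ago."
    step = 1 if subtype == "days" else 7
    return sentence, note_dt - timedelta(days=step * k1)


def _render_hour_relative(rng: random.Random, note_dt: datetime):
    subtype = rng.choice(("mil_today", "pm_last_night", "mil_yesterday"))
    if subtype == "mil_today":
        tod = note_dt.hour * 60 + note_dt.minute
        t = rng.randint(0, tod)
        sentence = f"c/o cp since {t // 60:02d}{t % 60:02d} today."
        return sentence, note_dt.replace(
            hour=t // 60, minute=t % 60, second=0, microsecond=0
        )
    if subtype == "pm_last_night":
        h = rng.randint(1, 11)
        minute = rng.choice((0, 30))
        tok = f"{h} pm" if minute == 0 else f"{h}:{minute:02d} pm"
        sentence = f"cp began last night at {tok} while watching TV."
        prev = note_dt - timedelta(days=1)
        return sentence, prev.replace(
            hour=h + 12, minute=minute, second=0, microsecond=0
        )
    hour, minute = rng.randint(0, 23), rng.randint(0, 59)
    sentence = f"pain started {hour:02d}{minute:02d} yesterday."
    prev = note_dt - timedelta(days=1)
    return sentence, prev.replace(hour=hour, minute=minute, second=0, microsecond=0)


_RENDERERS = {
    "clock_ampm": _render_clock_ampm,
    "hhmm_colon": _render_hhmm_colon,
    "military": _render_military,
    "daypart": _render_daypart,
    "wake": _render_wake,
    "days_ago": _render_days_ago,
    "weeks_ago": _render_weeks_ago,
    "range": _render_range,
    "hour_relative": _render_hour_relative,
}


def template_family(config: SynthConfig, index: int) -> str:
    """The template family note ``index`` draws from (deterministic)."""
    rng = random.Random(f"{config.seed}:{index}")
    families = sorted(config.category_weights)
    return rng.choices(families, [config.category_weights[f] for f in families])[0]


def generate_note(
    config: SynthConfig, index: int
) -> Tuple[ClinicalNote, OnsetAnnotation]:
    """Generate one synthetic note and its gold annotation.

    Deterministic given ``(config.seed, index)`` and independent of
    ``n_notes``, so corpora of different sizes share a common prefix.
    """
    rng = random.Random(f"{config.seed}:{index}")
    families = sorted(config.category_weights)
    family = rng.choices(families, [config.category_weights[f] for f in families])[0]

    start, end = config.note_datetime_window
    total_minutes = int((end - start).total_seconds() // 60)
    note_dt = start + timedelta(minutes=rng.randint(0, total_minutes))

    types = sorted(config.note_type_mix)
    note_type = NoteType(
        rng.choices(types, [config.note_type_mix[t] for t in types])[0]
    )

    sentence, gold = _RENDERERS[family](rng, note_dt)
    gold_candidates = [gold]

    parts = []
    if note_type is not NoteType.TRIAGE:
        age = rng.randint(35, 90)
        sex = rng.choice(("male", "female"))
        parts.append(rng.choice(_PREAMBLES).format(age=age, sex=sex))
    parts.append(sentence)

    if config.multi_episode:
        k = rng.randint(7, 14)
        parts.append(f" had a similar episode {k} days ago.")
        gold_candidates.append(note_dt - timedelta(days=k))

    if rng.random() < config.distractor_rate:
        parts.append(" " + rng.choice(DISTRACTOR_TEMPLATES).format(n=rng.randint(2, 9)))
    parts.append(" " + rng.choice(_FILLERS))

    # intermittent-symptom convention: the most recent episode is the onset
    gold = max(c for c in gold_candidates if c <= note_dt)

    note = ClinicalNote(
        note_id=f"synth-{config.seed}-{index:05d}",
        note_type=note_type,
        note_datetime=note_dt,
        text="".join(parts),
    )
    return note, OnsetAnnotation(note_id=note.note_id, gold_onset=gold)


_ISO = "%Y-%m-%d %H:%M"


def generate_corpus(config: SynthConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the full corpus as (notes table, annotations table).

    Columns match what the table readers consume: notes carry
    ``note_id, note_type, note_datetime, text`` and annotations carry
    ``note_id, onset_datetime``, with ISO-format minute-precision
    DateTimes.  Identical configs yield byte-identical tables.
    """
    notes, annotations = [], []
    for i in range(config.n_notes):
        note, ann = generate_note(config, i)
        notes.append(
            {
                "note_id": note.note_id,
                "note_type": note.note_type.value,
                "note_datetime": note.note_datetime.strftime(_ISO),
                "text": note.text,
            }
        )
        annotations.append(
            {
                "note_id": ann.note_id,
                "onset_datetime": ann.gold_onset.strftime(_ISO),
            }
        )
    notes_df = pd.DataFrame(
        notes, columns=["note_id", "note_type", "note_datetime", "text"]
    )
    ann_df = pd.DataFrame(annotations, columns=["note_id", "onset_datetime"])
    return notes_df, ann_df
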