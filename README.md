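# onsetdt

Rule-based extraction and normalization of **symptom-onset date and time**
from free-text clinical notes.

In acute coronary syndrome, the clock time a patient's chest pain began
drives staging, eligibility for time-sensitive therapy, and pre-hospital
delay research — but it usually lives only in narrative text ("c/o cp
which began last night at 9 pm", "pain since 0530 today", "woke with
chest pressure"). `onsetdt` is for clinical-NLP researchers and quality
teams who need that DateTime as structured data: it detects temporal
expressions in H&P, triage and ED-screening notes, and **anchors** each
one to an absolute `MM/DD/YYYY HH:MM` value using the note's own
timestamp as the reference.

## What it implements

Two extraction pipelines over a shared rule system:

- **Hybrid parser** (`onsetdt.hybrid`) — a primary scanner for
  human-readable phrases (relative words, "N days/weeks ago" offsets,
  clock times with am/pm, compounds like "last night at 9 pm", partial
  dates, daypart and wake phrases), with a fallback scanner for explicit
  numeric times that corrects punctuation ("4.45 am" → "4:45 am") and
  infers a missing meridiem. The fallback runs only when the primary
  scan finds nothing.
- **Pattern suite** (`onsetdt.regexsuite`) — six case-insensitive
  regular-expression families (HH:MM, H am/pm, 4-digit military time,
  clock+relative combos, dates, relative words/years) applied
  longest-match-first, labeling each expression with a format category.

Anchoring follows the AHA-derived conventions for unspecified onset
times (`onsetdt.rules`):

- a daypart/wake lexicon: morning → 07:00, lunch time → 12:00,
  afternoon → 15:00, dinner time → 18:00, evening → 22:00, awakening
  from sleep → 03:00, plus extended rows (midmorning → 09:00, deliberate
  morning wake-up → 06:00, after lunch → 13:00, after dinner → 19:00);
- backward offsets that keep the note's clock time: for a note dated
  01/01/2000 08:35, "1 day ago" → `12/31/1999 08:35`;
- time ranges resolved to the endpoint closest to (and not after) the
  note DateTime: "0200–0300" → 0300, "2–3 days ago" → 2 days;
- for intermittent symptoms, the most recent episode **prior to
  presentation** wins, and an onset never falls after the note DateTime.

Each pipeline runs in one of two modes. `faithful` reproduces the
behavior of naive off-the-shelf parsing, including its failure modes
(duplicate outputs for restated times, misread dose/count numerals such
as "6 mg" or "6 stents", and — for the pattern suite — no canonical
DateTime output at all). `extended` adds the distractor guard,
deduplication, and resolution to a single onset. A match-based evaluator
(`onsetdt.evaluation`) compares outputs against expert gold annotations
by exact canonical-string equality and tabulates match/output-count
distributions and expression-format counts. Because real annotated
notes are protected health information, a seeded synthetic-corpus
generator (`onsetdt.synth`) produces clinical-register sentences with
independently computed gold onsets for end-to-end testing.

## Worked example

```python
from datetime import datetime
from onsetdt import ClinicalNote, extract_onsets

note = ClinicalNote(
    note_id="ex1",
    note_type="TRIAGE",
    note_datetime=datetime(2000, 1, 6, 10, 0),
    text=("c/o cp which began last night at 9 pm while he was watching TV, "
          "denies being diaphoretic or nausea. has taken 6 nitro since last night. "
          "has had 6 stents in past. ekg in triage"),
)
result = extract_onsets(note, mode="extended")
for o in result.outputs:
    print(f"{o.expression.raw!r:28} stage={o.stage.value:8} -> {o.formatted}")
print("resolved onset:", result.resolved.formatted)
```

prints

```
'last night at 9 pm'         stage=primary  -> 01/05/2000 21:00
'last night'                 stage=lexicon  -> 01/05/2000 22:00
resolved onset: 01/05/2000 21:00
```

The compound phrase anchors 9 pm to the evening before the note
(01/05/2000 21:00). The standalone "last night" triggers the evening
lexicon rule (22:00 the previous day), but resolution prefers the
explicit clock time — the daypart mention restates the same episode.
The distractor numerals ("6 nitro", "6 stents") are guarded out in
extended mode.

The same flow from the shell, on a synthetic corpus:

```bash
onsetdt simulate --n 100 --seed 1 --out-notes notes.csv --out-annotations gold.csv
onsetdt extract notes.csv --pipeline hybrid --mode extended --out results.jsonl
onsetdt evaluate results.jsonl gold.csv --out report.json
# {"n_notes": 100, "n_matched": 100, "n_expressions": 100}
```

On supported-template synthetic notes the extended hybrid pipeline
recovers every gold onset exactly; see `docs/methods.md` for what that
does and does not say about real clinical text.

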