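# Methods

## Problem and model

`onsetdt` treats symptom-onset extraction as a two-stage problem:
**detection** of temporal expressions in note text, then **anchoring**
of each expression to an absolute DateTime relative to the note's own
timestamp. The output space is timezone-naive calendar DateTimes at
minute precision, rendered canonically as `MM/DD/YYYY HH:MM`; seconds
are always truncated because the canonical format — and the matching
criterion built on it — carries minutes only.

The core assumption throughout is that **onset precedes presentation**:
a patient describing symptoms at triage is describing something that
already happened. Every anchoring rule is therefore biased backward in
time — a bare clock time is placed on the note's calendar day only if
that yields a DateTime at or before the note, and otherwise on the
previous day; a partial date with no year takes the note's year unless
that lands in the future, in which case the prior year is used. When an
expression explicitly marked "today" still lands after the note's clock
time, the same backward rule applies and a warning is logged rather
than trusting the stated day.

## Detection

Both pipelines share a candidate-selection scheme: all pattern families
are matched case-insensitively, candidates are sorted by start
position, then by descending length, then by family precedence, and a
greedy sweep keeps non-overlapping matches. This makes "0530 today" one
combined clock-plus-relative expression rather than a military time
followed by a relative word, and lets "last night at 9 pm" beat the
standalone "last night" at the same start position. Detection is
deterministic: repeated runs on the same text yield identical spans.

The hybrid pipeline's primary scanner covers human-readable phrases;
its fallback scanner — run **only when the primary scan finds
nothing**, mirroring the orchestration the pipeline is modeled on (an
always-run-both flag exists) — covers explicit numeric times, including
dotted times ("4.45 am") whose separator is corrected to a colon. One
deliberate extension: the primary scanner also recognizes a 4-digit
military time preceded by a temporal cue word ("since 0530"). Without
it, a note containing both a relative phrase and an explicit military
time would lose the explicit time entirely, because the successful
primary scan suppresses the fallback.

Ambiguity conventions:

- A colon time with an hour of 13–23 or a leading zero ("20:30",
  "04:45") is read literally as 24-hour. A bare "7:30" with no meridiem
  goes through meridiem inference. The synthetic generator's 24-hour
  template family avoids bare 10–12 hours for exactly this reason: a
  rendered "11:30" is genuinely ambiguous between 11:30 and 23:30, and
  no rule can recover the intended half of day.
- Meridiem inference first looks for a daypart cue in a ±60-character
  window around the expression (morning-type cues force am,
  evening/night/meal cues force pm); failing that, it chooses among the
  four candidates {am, pm} × {note day, previous day} the one that
  anchors latest while staying at or before the note DateTime.
- A 4-digit token in 1900–2099 is read as a year unless a temporal cue
  immediately precedes it ("at 2004" is a time; "CABG in 2004" is a
  year). The ambiguity is logged.
- The distractor guard (extended mode only) rejects a bare numeral
  followed by a unit or count token (mg, mcg, stents, nitro, tablets,
  times, y/o, …). Faithful mode omits the guard deliberately so that
  the classic dose/count misread remains reproducible.

## Anchoring and resolution

Unspecified onset times use a ten-row daypart/wake lexicon shipped as a
plain-text table (`onsetdt/data/onset_lexicon.tsv`), with each row
tagged by provenance (`AHA` for the rows following the AHA key data
elements, `EXTENDED` for local additions). Wake-verb variants ("woke",
"awoke", "he woke up") with no morning context map to the
awakening-from-sleep row (03:00); "woke up" adjacent to "morning" maps
to the deliberate wake-up row (06:00). "Tonight", "last night" and
"overnight" reuse the evening row's clock time (22:00), with "last
night" shifted to the previous calendar day (a pm clock time in a
"last night" compound also anchors to the previous day; an am time may
be the early hours of the note's own day).

Relative offsets subtract whole units while preserving the note's clock
time; a week is exactly 7 days. Month offsets use calendar-month
arithmetic with day-of-month clamping — an extension beyond the
published day/week rules, flagged as such. Offsets are accepted for any
non-negative count (the published rule is only illustrated to 4 days);
offsets beyond 30 days resolve normally but emit a log warning, and
results before the year 1900 raise a range error. Ranges resolve to the
endpoint whose anchored DateTime is closest to, and not after, the note
DateTime — the later clock time in a clock range, the smaller offset in
an "ago" range; equal endpoints return the first. A range neither of
whose endpoints anchors at or before the note raises a flagged-result
error rather than guessing.

Extended-mode resolution deduplicates identical canonical strings,
drops anchors after the note DateTime, and applies the
most-recent-episode rule. One refinement: when both explicit
(clock/offset-derived) and lexicon-default outputs survive, resolution
considers only the explicit ones. A daypart word co-occurring with an
explicit time almost always restates the same episode, and resolving
over all candidates would let the 22:00 evening default outrank an
explicit "9 pm". Notes with only lexicon outputs resolve among those.

Faithful mode performs none of this: every anchored output is emitted
in document order, duplicates included, and the pattern-suite pipeline
emits **no** anchored outputs at all — it stops at labeled expressions,
reproducing the observed behavior of the pattern-only approach.

## Evaluation

A note is matched when any output equals the gold onset at minute
precision; equality is semantic (on the DateTime) and rendered
canonically, which for zero-padded strings coincides with exact string
match. An optional ±N-minute tolerance exists and is off by default. A
note with several matching outputs counts as matched once. Reports
tabulate (note type × matched × output count) — the counts always sum
to the number of evaluated notes — and expression format categories
(HH:MM, H am/pm, military, clock+relative, year, other) with example
strings, summing to the total expression count.

## Synthetic corpus

The generator emulates the study conditions the package is tested
under: short clinical-register sentences ("c/o", "cp", "pt"), one onset
expression per note drawn from nine template families (12-hour clock,
24-hour colon time, military time, daypart word, wake phrase, days-ago,
weeks-ago, range, clock+relative), optional distractor numerics, and an
optional second, earlier episode to exercise the most-recent rule.
Defaults: 200 notes; uniform family weights; distractor rate 1/3
(dose/count numerals appear at roughly that rate in the example
sentences the templates are styled on); a note-type mix of 49:19:3
H&P:Triage:ED-screening, the composition of the 71-note pilot setting
being emulated; note DateTimes uniform over calendar year 2024. Gold
onsets are computed by generator-side calendar arithmetic that shares
no code with the rule module, so extractor-versus-gold agreement is a
genuine cross-check, and generation is deterministic per (seed, index)
and independent of corpus size.

The generator does **not** emulate full note length or section
structure, misspellings, contradictory or absent onset statements, or
expressions outside the supported families. Perfect gold recovery on
this corpus (asserted by the test suite at n=200) therefore
demonstrates that the detection and anchoring rules are internally
consistent — not that the pipeline achieves any particular accuracy on
real clinical notes, where roughly half of notes resisted exact
matching in the pilot setting this package re-implements.

## Problem sizes and determinism

Property suites run at sizes chosen to exercise every template family
and code path several times over: 200-note corpora for recovery and
conservation checks, 100–150 notes for distractor and multi-episode
invariants, 100 random anchors × offsets 0–60 days for the
calendar-arithmetic oracle. Hypothesis-based tests run derandomized.
The acceptance script seeds all randomness from its `--seed` argument;
the worked-example quantities it reports are themselves deterministic.

## Known limitations

- Durations ("chest pain for 3 hours") are not distinguished from
  offsets; "for 3 hours" is simply not detected (no "ago").
- Negated or hypothetical time mentions ("denies pain since morning")
  are not filtered; there is no assertion/negation model.
- Bare 10–12 o'clock colon times without meridiem cues resolve by the
  latest-not-after rule, which can be wrong for genuinely ambiguous
  text.
- Timezones, daylight-saving transitions and sub-minute precision are
  out of scope by design.
- The clinical judgment of which episode is "ischemic" is not modeled;
  only temporal recency is.
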