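from datetime import datetime

import pytest
from hypothesis import settings

from onsetdt import io as io_mod
from onsetdt.types import ClinicalNote, NoteType

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def example_notes():
    """The bundled worked-example sentences, keyed by note_id."""
    notes = io_mod.read_notes_table(io_mod.example_notes_path())
    return {n.note_id: n for n in notes}


@pytest.fixture
def make_note():
    def _make(text, note_dt=datetime(2000, 1, 5, 10, 0), note_type=NoteType.TRIAGE,
              note_id="n1"):
        return ClinicalNote(note_id=note_id, note_type=note_type,
                            note_datetime=note_dt, text=text)

    return _make
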