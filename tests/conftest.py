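"""Shared fixtures: tiny hand-built corpora plus session-scoped simulations."""

from __future__ import annotations

from datetime import datetime

import pytest

from oncolex.lexicon import LexiconEntry, SentimentLexicon
from oncolex.textprep import NoteRecord, StopWordList


def make_note(note_id: str, text: str, patient: str = "p1", when: datetime | None = None) -> NoteRecord:
    return NoteRecord.from_text(note_id, patient, when or datetime(2020, 1, 1, 12, 0), text)


def make_lexicon(scores: dict[str, float], source: str = "original") -> SentimentLexicon:
    return SentimentLexicon.from_entries(
        LexiconEntry(w, s, source=source) for w, s in scores.items()
    )


@pytest.fixture
def toy_lexicon() -> SentimentLexicon:
    return make_lexicon(
        {
            "good": 7.0,
            "bad": 3.0,
            "stable": 6.2,
            "positive": 7.8,
            "negative": 2.4,
            "pain": 2.2,
            "happy": 8.0,
            "calm": 6.5,
        }
    )


@pytest.fixture
def no_stops() -> StopWordList:
    return StopWordList(frozenset(), "empty")


@pytest.fixture
def small_stops() -> StopWordList:
    return StopWordList(frozenset({"the", "is", "a", "and"}), "toy")


@pytest.fixture(scope="session")
def desk_sim():
    """Default desk-scale simulation bundle, shared across tests."""
    from oncolex.synthetic_data import SimConfig, simulate

    return simulate(SimConfig.desk(seed=7))
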