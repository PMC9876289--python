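"""Tokenization and stop-word handling shared by selection and scoring.

Tokens are lowercased maximal runs of letters and digits, with apostrophes
kept when they sit between two such characters ("don't" stays one token).
No stemming or lemmatization is applied: "medications" is not reduced to
"medication", so lexicon lookups are exact surface matches.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from datetime import datetime
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "NoteRecord",
    "StopWordList",
    "tokenize",
    "remove_stopwords",
    "default_stopwords",
    "read_stopwords",
    "read_notes",
    "write_notes",
]

# letters/digits (no underscore), optionally joined by internal apostrophes
_TOKEN_RE = re.compile(r"[^\W_]+(?:'[^\W_]+)*")


@dataclass(frozen=True)
class NoteRecord:
    """One clinical note with its derived token stream."""

    note_id: str
    patient_id: str
    timestamp: datetime
    text: str
    tokens: tuple[str, ...] = field(default=())

    @classmethod
    def from_text(cls, note_id: str, patient_id: str, timestamp: datetime, text: str) -> "NoteRecord":
        return cls(note_id, patient_id, timestamp, text, tuple(tokenize(text)))


@dataclass(frozen=True)
class StopWordList:
    words: frozenset[str]
    label: str = ""

    def __contains__(self, word: str) -> bool:
        return word in self.words

    def __len__(self) -> int:
        return len(self.words)


def tokenize(text: str) -> list[str]:
    """Lowercase and split into tokens; punctuation and whitespace separate.

    Digits are kept inside tokens ("10mg" -> ["10mg"]); such tokens simply
    never match a lexicon word.
    """
    return _TOKEN_RE.findall(text.lower())


def remove_stopwords(tokens: Iterable[str], stops: StopWordList) -> list[str]:
    """Order-preserving removal of stop words from a token stream."""
    sw = stops.words
    return [t for t in tokens if t not in sw]


def read_stopwords(path: str | Path, label: str | None = None) -> StopWordList:
    """Read a plain-text stop list, one word per line; '#' lines are comments."""
    path = Path(path)
    words = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        w = line.strip().lower()
        if w and not w.startswith("#"):
            words.add(w)
    return StopWordList(frozenset(words), label or str(path))


def default_stopwords() -> StopWordList:
    """The packaged standard English stop list."""
    text = resources.files("oncolex.data").joinpath("stopwords_en.txt").read_text(encoding="utf-8")
    words = {w.strip().lower() for w in text.splitlines() if w.strip() and not w.startswith("#")}
    return StopWordList(frozenset(words), "oncolex:stopwords_en")


def read_notes(path: str | Path) -> list[NoteRecord]:
    """Read notes from JSONL (one object per line) or CSV.

    Both carriers use the columns/keys ``note_id, patient_id, timestamp,
    text`` with ISO-8601 timestamps. The format is chosen by extension
    (.jsonl/.json -> JSONL, anything else -> CSV).
    """
    path = Path(path)
    notes: list[NoteRecord] = []
    seen: set[str] = set()

    def add(note_id: str, patient_id: str, ts: str, text: str) -> None:
        if note_id in seen:
            raise ValueError(f"duplicate note_id {note_id!r} in {path}")
        seen.add(note_id)
        notes.append(NoteRecord.from_text(note_id, patient_id, datetime.fromisoformat(ts), text))

    if path.suffix.lower() in {".jsonl", ".json"}:
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                obj = json.loads(line)
                add(str(obj["note_id"]), str(obj["patient_id"]), obj["timestamp"], obj["text"])
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                add(str(row["note_id"]), str(row["patient_id"]), row["timestamp"], row["text"])
    return notes


def write_notes(notes: Iterable[NoteRecord], path: str | Path) -> None:
    """Write notes as JSONL with ISO-8601 timestamps."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for n in notes:
            fh.write(
                json.dumps(
                    {
                        "note_id": n.note_id,
                        "patient_id": n.patient_id,
                        "timestamp": n.timestamp.isoformat(),
                        "text": n.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
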