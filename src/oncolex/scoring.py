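"""Per-note and aggregate sentiment scores under a lensed lexicon.

A note's score is the frequency-weighted mean of the lexicon scores of its
tokens: with f_w the count of word w among the note's tokens (after
stop-word removal) and h_w its lensed-lexicon score,

    score = sum_w f_w * h_w / sum_w f_w ,

taken over the words present in the lensed lexicon; unscored tokens are
ignored entirely. This equals a plain per-token mean over scorable tokens.
Notes with no scorable token have no score and are excluded from
aggregates (their count is reported by `score_corpus`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from datetime import datetime
from typing import Callable, Iterable, Mapping, Sequence

from .lexicon import SentimentLexicon
from .textprep import NoteRecord, StopWordList, remove_stopwords

__all__ = ["NoteScore", "score_note", "score_corpus", "daily_mean"]


@dataclass(frozen=True)
class NoteScore:
    note_id: str
    patient_id: str
    timestamp: datetime
    score: float | None
    n_scored_tokens: int

    @property
    def defined(self) -> bool:
        return self.n_scored_tokens > 0


def score_note(note: NoteRecord, lensed: SentimentLexicon, stops: StopWordList) -> NoteScore:
    """Frequency-weighted mean lexicon score of one note."""
    freqs = Counter(remove_stopwords(note.tokens, stops))
    num = 0.0
    den = 0
    get = lensed.entries.get
    for w, f in freqs.items():
        e = get(w)
        if e is not None:
            num += f * e.score
            den += f
    score = num / den if den else None
    return NoteScore(note.note_id, note.patient_id, note.timestamp, score, den)


def score_corpus(
    corpus: Iterable[NoteRecord],
    lensed: SentimentLexicon,
    stops: StopWordList,
) -> tuple[list[NoteScore], int]:
    """Score every note; returns (defined scores, count of unscorable notes)."""
    defined: list[NoteScore] = []
    n_unscorable = 0
    for note in corpus:
        s = score_note(note, lensed, stops)
        if s.defined:
            defined.append(s)
        else:
            n_unscorable += 1
    return defined, n_unscorable


def daily_mean(
    scores: Sequence[NoteScore],
    day_index: Mapping[str, int] | Callable[[NoteScore], int],
) -> dict[int, tuple[float, int]]:
    """Unweighted per-day mean of note scores.

    Each note counts once regardless of length. `day_index` maps a note
    (by note_id, or via a callable on the NoteScore) to an integer day.
    """
    idx = day_index if callable(day_index) else (lambda s: day_index[s.note_id])
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for s in scores:
        if s.score is None:
            raise ValueError(f"undefined score for note {s.note_id!r}")
        d = idx(s)
        sums[d] = sums.get(d, 0.0) + s.score
        counts[d] = counts.get(d, 0) + 1
    return {d: (sums[d] / counts[d], counts[d]) for d in sorted(sums)}
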