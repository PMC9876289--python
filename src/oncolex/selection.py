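"""Data-driven selection of high-importance words for expert re-scoring.

Two mechanisms feed the selection, both computed over a (possibly sampled)
note corpus:

1. *Novel words*: tokens absent from the base lexicon (and not stop words),
   counted by frequency. These carry no score at all, so their context
   mismatch is maximal by construction and they receive delta = 1.
2. *Ambient mismatch*: for every lexicon word ("anchor") occurring in the
   corpus, the mean lexicon score of the tokens within a +/- `window`
   positions neighborhood of each occurrence — the ambient sentiment
   h_amb. The mismatch is delta = |h - h_amb|, large when a word's
   domain usage disagrees with its out-of-domain rating (e.g. "positive"
   in an oncology note).

Candidates are ranked by frequency x delta and truncated to the top K
(default 200), balancing prominence in the notes against poor context
matching. The coverage curve reports the cumulative fraction of (non-stop)
note text the top-r selected words account for.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .lexicon import SentimentLexicon
from .textprep import NoteRecord, StopWordList

__all__ = [
    "AmbientRecord",
    "SelectionResult",
    "count_nonlexicon_words",
    "ambient_sentiment",
    "compute_deltas",
    "rank_and_truncate",
    "coverage_curve",
    "sample_notes",
]


@dataclass(frozen=True)
class AmbientRecord:
    """Per-candidate calibration statistics.

    ``anchor_score`` is the lexicon score h (None for novel words),
    ``ambient_score`` the windowed context mean h_amb (None for novel
    words), ``delta`` = |h - h_amb| (artificially 1 for novel words) and
    ``rank_product`` = frequency x delta.
    """

    word: str
    frequency: int
    delta: float
    anchor_score: float | None = None
    ambient_score: float | None = None

    @property
    def rank_product(self) -> float:
        return self.frequency * self.delta


@dataclass
class SelectionResult:
    ranked: list[AmbientRecord]
    selected: list[str]
    K: int
    coverage: list[tuple[int, float]]


def sample_notes(corpus: Sequence[NoteRecord], n: int | None, seed: int) -> list[NoteRecord]:
    """Uniform without-replacement subsample of the corpus (None = all)."""
    if n is None or n >= len(corpus):
        return list(corpus)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(corpus), size=n, replace=False)
    return [corpus[i] for i in sorted(idx)]


def count_nonlexicon_words(
    corpus: Sequence[NoteRecord],
    lex: SentimentLexicon,
    stops: StopWordList,
) -> dict[str, int]:
    """Token counts of corpus words that are neither in the lexicon nor stop words."""
    counts: Counter[str] = Counter()
    sw = stops.words
    for note in corpus:
        counts.update(t for t in note.tokens if t not in lex and t not in sw)
    return dict(counts)


def ambient_sentiment(
    corpus: Sequence[NoteRecord],
    lex: SentimentLexicon,
    window: int = 5,
    stops: StopWordList | None = None,
) -> dict[str, float]:
    """Windowed context score h_amb for every lexicon word in the corpus.

    For each occurrence of an anchor (a token present in `lex`), up to
    `window` tokens before and after within the same note are collected;
    the anchor's ambient score is the mean lexicon score of those
    neighbors that are themselves in `lex`, pooled over all occurrences.
    Anchors whose every neighborhood is unscored get no entry.

    By default the window runs over raw token positions (stop words occupy
    positions; they contribute a score only if they are lexicon words).
    Pass `stops` to remove stop words before positioning instead.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    score_map = lex.scores()
    sums: Counter[str] = Counter()
    counts: Counter[str] = Counter()
    for note in corpus:
        tokens = note.tokens
        if stops is not None:
            tokens = tuple(t for t in tokens if t not in stops.words)
        n = len(tokens)
        if n == 0:
            continue
        scores = np.fromiter(
            (score_map.get(t, np.nan) for t in tokens), dtype=float, count=n
        )
        scored = ~np.isnan(scores)
        # prefix sums over scored neighbor values/counts for O(1) window sums
        csum = np.concatenate(([0.0], np.cumsum(np.where(scored, scores, 0.0))))
        ccnt = np.concatenate(([0], np.cumsum(scored.astype(np.int64))))
        for i in np.flatnonzero(scored):
            lo = max(0, i - window)
            hi = min(n, i + window + 1)
            s = csum[hi] - csum[lo] - scores[i]
            c = ccnt[hi] - ccnt[lo] - 1
            if c > 0:
                w = tokens[i]
                sums[w] += s
                counts[w] += c
    return {w: sums[w] / counts[w] for w in counts}


def compute_deltas(
    lex: SentimentLexicon,
    ambient: Mapping[str, float],
    novel_words: Mapping[str, int],
    lexicon_frequencies: Mapping[str, int] | None = None,
) -> list[AmbientRecord]:
    """Combine the two candidate lists into scored records.

    Lexicon words with an ambient score get delta = |h - h_amb|; novel
    words get delta = 1. ``lexicon_frequencies`` supplies corpus token
    counts for anchors (0 when missing, which zeroes their rank product).
    """
    freqs = lexicon_frequencies or {}
    records: list[AmbientRecord] = []
    for w, amb in ambient.items():
        h = lex.score(w)
        records.append(
            AmbientRecord(
                word=w,
                frequency=int(freqs.get(w, 0)),
                delta=abs(h - amb),
                anchor_score=h,
                ambient_score=amb,
            )
        )
    for w, f in novel_words.items():
        records.append(AmbientRecord(word=w, frequency=int(f), delta=1.0))
    return records


def rank_and_truncate(records: Sequence[AmbientRecord], K: int = 200) -> SelectionResult:
    """Sort by rank product (descending) and keep the top K.

    Ties break by frequency descending, then lexicographic word order, so
    the selection is deterministic.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    ranked = sorted(records, key=lambda r: (-r.rank_product, -r.frequency, r.word))
    selected = [r.word for r in ranked[:K]]
    return SelectionResult(ranked=ranked, selected=selected, K=K, coverage=[])


def coverage_curve(
    selected: Sequence[str],
    corpus: Sequence[NoteRecord],
    stops: StopWordList,
) -> list[tuple[int, float]]:
    """Cumulative fraction of non-stop corpus tokens matched by the top-r words."""
    counts: Counter[str] = Counter()
    total = 0
    sw = stops.words
    for note in corpus:
        for t in note.tokens:
            if t not in sw:
                counts[t] += 1
                total += 1
    if total == 0:
        raise ValueError("corpus has no non-stop tokens")
    curve: list[tuple[int, float]] = []
    cum = 0
    for r, w in enumerate(selected, start=1):
        cum += counts.get(w, 0)
        curve.append((r, cum / total))
    return curve


def candidates_to_rows(result: SelectionResult) -> list[dict]:
    """Rows for the candidate CSV (usable directly as an SME survey sheet)."""
    sel = set(result.selected)
    return [
        {
            "word": r.word,
            "frequency": r.frequency,
            "anchor_score": "" if r.anchor_score is None else r.anchor_score,
            "ambient_score": "" if r.ambient_score is None else r.ambient_score,
            "delta": r.delta,
            "rank_product": r.rank_product,
            "selected": int(r.word in sel),
        }
        for r in result.ranked
    ]
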