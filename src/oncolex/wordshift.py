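"""Word-shift decomposition of a difference in mean sentiment.

With p_w^(c) the relative frequency of word w among the scorable tokens of
corpus c, the token-pooled mean of a corpus is H^(c) = sum_w p_w^(c) h_w.
Centering on the reference mean H_ref, the difference decomposes exactly
into per-word contributions

    contribution(w) = (h_w - H_ref) * (p_w^(comp) - p_w^(ref)),
    sum_w contribution(w) = H_comp - H_ref,

because the relative frequencies each sum to one. A word scored above the
reference mean that is more common in the comparison corpus contributes
positively, and vice versa — the standard reference-centered shift used
with 1-9 happiness lexicons.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .lexicon import SentimentLexicon
from .textprep import NoteRecord, StopWordList, remove_stopwords

__all__ = ["ShiftResult", "word_shift", "write_shift_csv"]


@dataclass
class ShiftResult:
    reference_mean: float
    comparison_mean: float
    contributions: dict[str, float]
    percent: dict[str, float]
    p_ref: dict[str, float]
    p_comp: dict[str, float]
    scores: dict[str, float]

    def top(self, n: int = 40) -> list[tuple[str, float]]:
        """The n words with largest |contribution|, descending."""
        return sorted(self.contributions.items(), key=lambda kv: (-abs(kv[1]), kv[0]))[:n]


def _scored_freqs(
    corpus: Iterable[NoteRecord], lensed: SentimentLexicon, stops: StopWordList
) -> Counter[str]:
    freqs: Counter[str] = Counter()
    for note in corpus:
        freqs.update(t for t in remove_stopwords(note.tokens, stops) if t in lensed)
    return freqs


def word_shift(
    reference: Sequence[NoteRecord],
    comparison: Sequence[NoteRecord],
    lensed: SentimentLexicon,
    stops: StopWordList,
) -> ShiftResult:
    """Decompose comparison-minus-reference pooled mean into word contributions."""
    f_ref = _scored_freqs(reference, lensed, stops)
    f_comp = _scored_freqs(comparison, lensed, stops)
    n_ref = sum(f_ref.values())
    n_comp = sum(f_comp.values())
    if n_ref == 0 or n_comp == 0:
        raise ValueError("each corpus must contain at least one scorable token")

    words = set(f_ref) | set(f_comp)
    h = {w: lensed.score(w) for w in words}
    p_ref = {w: f_ref.get(w, 0) / n_ref for w in words}
    p_comp = {w: f_comp.get(w, 0) / n_comp for w in words}
    h_ref = sum(p_ref[w] * h[w] for w in words)
    h_comp = sum(p_comp[w] * h[w] for w in words)

    contributions = {w: (h[w] - h_ref) * (p_comp[w] - p_ref[w]) for w in words}
    total_abs = sum(abs(c) for c in contributions.values())
    percent = {
        w: (100.0 * c / total_abs if total_abs > 0 else 0.0) for w, c in contributions.items()
    }
    return ShiftResult(h_ref, h_comp, contributions, percent, p_ref, p_comp, h)


def write_shift_csv(result: ShiftResult, path: str | Path, top_n: int | None = None) -> None:
    """Full (or top-N by |contribution|) shift table as CSV."""
    rows = result.top(len(result.contributions) if top_n is None else top_n)
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["word", "h", "p_ref", "p_comp", "contribution", "percent"])
        for w, c in rows:
            writer.writerow(
                [
                    w,
                    repr(result.scores[w]),
                    repr(result.p_ref[w]),
                    repr(result.p_comp[w]),
                    repr(c),
                    repr(result.percent[w]),
                ]
            )
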