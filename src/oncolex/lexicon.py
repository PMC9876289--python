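"""Sentiment lexicons on the 1-9 happiness scale.

A lexicon maps lowercase words to happiness scores (1 = most unhappy,
9 = most happy), optionally with an inter-rater standard deviation.
This module loads lexicons from TSV/CSV carriers, merges a base list
with a subject-matter-expert (SME) re-scoring table, and applies the
neutral-band "lens" that drops uninformative near-neutral words before
scoring.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

__all__ = [
    "LexiconEntry",
    "SentimentLexicon",
    "read_lexicon",
    "write_lexicon",
    "read_sme_table",
    "sme_table_stats",
    "merge_recalibration",
    "apply_lens",
]

Source = Literal["original", "sme_rescored", "sme_new"]

SCORE_MIN = 1.0
SCORE_MAX = 9.0


class LexiconError(ValueError):
    """Malformed lexicon input (bad score, duplicate word, bad layout)."""


@dataclass(frozen=True)
class LexiconEntry:
    """One word with its happiness score.

    Parameters
    ----------
    word
        Lowercase token; no whitespace.
    score
        Happiness on the 1-9 scale.
    sd
        Optional nonnegative inter-rater standard deviation.
    source
        Provenance: ``original`` (base list), ``sme_rescored`` (base word
        re-scored by SMEs) or ``sme_new`` (word added by SMEs).
    """

    word: str
    score: float
    sd: float | None = None
    source: Source = "original"

    def __post_init__(self) -> None:
        if not self.word or self.word != self.word.lower() or any(c.isspace() for c in self.word):
            raise LexiconError(f"invalid word {self.word!r}: must be nonempty lowercase, no whitespace")
        if not (SCORE_MIN <= self.score <= SCORE_MAX):
            raise LexiconError(f"score {self.score} for {self.word!r} outside [{SCORE_MIN}, {SCORE_MAX}]")
        if self.sd is not None and self.sd < 0:
            raise LexiconError(f"negative sd {self.sd} for {self.word!r}")


@dataclass
class SentimentLexicon:
    """A word -> score map with one entry per distinct word."""

    entries: dict[str, LexiconEntry] = field(default_factory=dict)
    name: str = ""

    @classmethod
    def from_entries(cls, entries: Iterable[LexiconEntry], name: str = "") -> "SentimentLexicon":
        out: dict[str, LexiconEntry] = {}
        for e in entries:
            if e.word in out:
                raise LexiconError(f"duplicate word {e.word!r} in lexicon {name!r}")
            out[e.word] = e
        return cls(out, name)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self.entries.values())

    def score(self, word: str) -> float:
        return self.entries[word].score

    def get_score(self, word: str) -> float | None:
        e = self.entries.get(word)
        return None if e is None else e.score

    def scores(self) -> dict[str, float]:
        """Plain word -> score dict (a copy)."""
        return {w: e.score for w, e in self.entries.items()}

    def mean_score(self) -> float:
        """Unweighted mean score over all words."""
        if not self.entries:
            raise LexiconError("mean of empty lexicon")
        return sum(e.score for e in self.entries.values()) / len(self.entries)


def _parse_score(raw: str, row: int, path: Path) -> float:
    try:
        score = float(raw)
    except ValueError:
        raise LexiconError(f"{path}:{row}: non-numeric score {raw!r}") from None
    if not (SCORE_MIN <= score <= SCORE_MAX):
        raise LexiconError(f"{path}:{row}: score {score} outside [{SCORE_MIN}, {SCORE_MAX}]")
    return score


def read_lexicon(
    path: str | Path,
    dialect: Literal["two_column", "labmt_full"] = "two_column",
    name: str | None = None,
    source: Source = "original",
) -> SentimentLexicon:
    """Read a lexicon from a TSV file.

    ``two_column`` expects a header and ``word<TAB>score[<TAB>sd]`` rows.
    ``labmt_full`` expects the published labMT layout (word, rank,
    happiness_average, happiness_sd, then corpus-rank columns); only the
    word and average/sd columns are consumed.
    """
    path = Path(path)
    entries: dict[str, LexiconEntry] = {}
    with path.open(encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise LexiconError(f"{path}: empty file")
        if dialect == "two_column":
            word_i, score_i, sd_i = 0, 1, (2 if len(header) > 2 else None)
        elif dialect == "labmt_full":
            # published layout: word  rank  happiness_average  happiness_sd  ...
            lowered = [h.strip().lower() for h in header]
            word_i = lowered.index("word") if "word" in lowered else 0
            score_i = lowered.index("happiness_average") if "happiness_average" in lowered else 2
            sd_i = lowered.index("happiness_sd") if "happiness_sd" in lowered else 3
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        for row_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            word = row[word_i].strip().lower()
            score = _parse_score(row[score_i], row_no, path)
            sd = None
            if sd_i is not None and sd_i < len(row) and row[sd_i].strip():
                sd = float(row[sd_i])
            if word in entries:
                raise LexiconError(f"{path}:{row_no}: duplicate word {word!r}")
            entries[word] = LexiconEntry(word, score, sd, source)
    return SentimentLexicon(entries, name or path.stem)


def write_lexicon(lex: SentimentLexicon, path: str | Path) -> None:
    """Write in the two_column dialect (word, score, sd; sd blank if absent)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["word", "score", "sd"])
        for word in sorted(lex.entries):
            e = lex.entries[word]
            writer.writerow([e.word, repr(e.score), "" if e.sd is None else repr(e.sd)])


def read_sme_table(
    path: str | Path,
    consensus: Literal["mean", "median"] = "mean",
    name: str | None = None,
) -> SentimentLexicon:
    """Read an SME re-scoring table (CSV).

    Two layouts are auto-detected from the header:

    * ``word, rater_1, ..., rater_k`` — per-rater scores; the consensus
      score is their mean (or median) and ``sd`` the sample standard
      deviation across raters.
    * ``word, score[, sd]`` — pre-aggregated.

    Entries are tagged ``sme_new``; :func:`merge_recalibration` re-tags the
    ones that override a base word as ``sme_rescored``.
    """
    import statistics

    path = Path(path)
    entries: dict[str, LexiconEntry] = {}
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise LexiconError(f"{path}: empty file")
        lowered = [h.strip().lower() for h in header]
        per_rater = len(lowered) > 1 and all(h.startswith("rater") for h in lowered[1:])
        for row_no, row in enumerate(reader, start=2):
            if not row:
                continue
            word = row[0].strip().lower()
            if per_rater:
                vals = [float(v) for v in row[1:] if v.strip()]
                if not vals:
                    raise LexiconError(f"{path}:{row_no}: no rater scores for {word!r}")
                score = statistics.mean(vals) if consensus == "mean" else statistics.median(vals)
                sd = statistics.stdev(vals) if len(vals) > 1 else 0.0
            else:
                score = _parse_score(row[1], row_no, path)
                sd = float(row[2]) if len(row) > 2 and row[2].strip() else None
            if word in entries:
                raise LexiconError(f"{path}:{row_no}: duplicate word {word!r}")
            entries[word] = LexiconEntry(word, score, sd, "sme_new")
    return SentimentLexicon(entries, name or path.stem)


def sme_table_stats(sme: SentimentLexicon) -> tuple[float, float]:
    """(mean consensus score, mean per-word inter-rater SD) over an SME table.

    Words without an SD are excluded from the SD mean.
    """
    scores = [e.score for e in sme]
    sds = [e.sd for e in sme if e.sd is not None]
    if not scores:
        raise LexiconError("empty SME table")
    mean_score = sum(scores) / len(scores)
    mean_sd = sum(sds) / len(sds) if sds else float("nan")
    return mean_score, mean_sd


def merge_recalibration(base: SentimentLexicon, sme: SentimentLexicon) -> SentimentLexicon:
    """Overlay SME re-scores on a base lexicon.

    Every SME word enters with its SME score, tagged ``sme_rescored`` when
    it overrides a base word and ``sme_new`` otherwise; base words the SMEs
    did not touch keep their original score. The merged size is therefore
    ``|base| + |sme \\ base|``.
    """
    merged: dict[str, LexiconEntry] = {}
    for w, e in base.entries.items():
        merged[w] = LexiconEntry(w, e.score, e.sd, "original")
    for w, e in sme.entries.items():
        src: Source = "sme_rescored" if w in base.entries else "sme_new"
        merged[w] = LexiconEntry(w, e.score, e.sd, src)
    return SentimentLexicon(merged, name=f"{base.name}+{sme.name}" if base.name or sme.name else "merged")


def apply_lens(
    lex: SentimentLexicon,
    neutral_lo: float = 4.0,
    neutral_hi: float = 6.0,
) -> SentimentLexicon:
    """Drop near-neutral original words; keep every SME-scored word.

    Original-list words with ``neutral_lo < score < neutral_hi`` (bounds
    exclusive) are removed so informative words dominate the note score.
    Words scored by the SMEs are retained regardless of score, because in
    this domain their re-calibrated rating is informative even when
    near-neutral.
    """
    if not neutral_lo <= neutral_hi:
        raise ValueError("neutral_lo must not exceed neutral_hi")
    kept = {
        w: e
        for w, e in lex.entries.items()
        if e.source != "original" or not (neutral_lo < e.score < neutral_hi)
    }
    return SentimentLexicon(kept, name=f"{lex.name}|lens({neutral_lo},{neutral_hi})")
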