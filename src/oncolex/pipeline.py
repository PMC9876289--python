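"""End-to-end orchestration: calibration selection, scoring, analyses.

A RunConfig gathers all file paths and tunables; every randomized stage
consumes an explicit seed recorded (with a hash of the config) in each
output, so reruns with an identical config are byte-identical.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import date
from pathlib import Path
from typing import Any

import yaml

from . import comparative, scoring, selection, wordshift
from .lexicon import SentimentLexicon, apply_lens, merge_recalibration, read_lexicon, read_sme_table
from .textprep import StopWordList, default_stopwords, read_notes, read_stopwords

__all__ = ["RunConfig", "run_calibration", "run_full", "load_config"]


@dataclass
class RunConfig:
    notes_path: str
    lexicon_path: str
    out_dir: str
    sme_path: str | None = None
    stopwords_path: str | None = None
    labs_path: str | None = None
    treatments_path: str | None = None
    medication_matrix_path: str | None = None
    lexicon_dialect: str = "two_column"
    neutral_lo: float = 4.0
    neutral_hi: float = 6.0
    window: int = 5
    K: int = 200
    sample_n: int | None = None
    window_days: int = 7
    horizon_days: int = 42
    alpha: float = 0.05
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def validate(self) -> None:
        required = {"notes": self.notes_path, "lexicon": self.lexicon_path}
        optional = {
            "sme": self.sme_path,
            "stopwords": self.stopwords_path,
            "labs": self.labs_path,
            "treatments": self.treatments_path,
            "medication_matrix": self.medication_matrix_path,
        }
        missing = [f"{k}: {v}" for k, v in required.items() if not Path(v).exists()]
        missing += [f"{k}: {v}" for k, v in optional.items() if v is not None and not Path(v).exists()]
        if missing:
            raise FileNotFoundError("missing input file(s): " + "; ".join(missing))


def load_config(path: str | Path, **overrides: Any) -> RunConfig:
    """YAML config; keyword overrides win over file keys."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**raw)


def _stops(cfg: RunConfig) -> StopWordList:
    return read_stopwords(cfg.stopwords_path) if cfg.stopwords_path else default_stopwords()


def _provenance(cfg: RunConfig) -> dict:
    return {"config_hash": cfg.config_hash(), "seed": cfg.seed, "stopwords": _stops(cfg).label}


def run_calibration(cfg: RunConfig) -> selection.SelectionResult:
    """Sample notes, run both selection mechanisms, rank, write candidates CSV.

    Stages: sample -> count non-lexicon words -> ambient sentiment ->
    deltas -> frequency x delta ranking -> coverage curve. The candidate
    CSV doubles as an SME survey sheet.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stops = _stops(cfg)
    lex = read_lexicon(cfg.lexicon_path, dialect=cfg.lexicon_dialect)  # type: ignore[arg-type]
    corpus = read_notes(cfg.notes_path)
    sample = selection.sample_notes(corpus, cfg.sample_n, cfg.seed)

    novel = selection.count_nonlexicon_words(sample, lex, stops)
    ambient = selection.ambient_sentiment(sample, lex, window=cfg.window)
    from collections import Counter

    lex_freqs: Counter[str] = Counter()
    for note in sample:
        lex_freqs.update(t for t in note.tokens if t in lex)
    records = selection.compute_deltas(lex, ambient, novel, lex_freqs)
    result = selection.rank_and_truncate(records, K=cfg.K)
    result.coverage = selection.coverage_curve(result.selected, sample, stops)

    with (out / "calibration_candidates.csv").open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(
            fh,
            fieldnames=["word", "frequency", "anchor_score", "ambient_score", "delta", "rank_product", "selected"],
        )
        writer.writeheader()
        writer.writerows(selection.candidates_to_rows(result))
    with (out / "coverage_curve.csv").open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["rank", "cumulative_coverage"])
        writer.writerows([(r, repr(c)) for r, c in result.coverage])
    (out / "calibration_log.json").write_text(
        json.dumps(
            {**_provenance(cfg), "n_notes_sampled": len(sample), "n_candidates": len(result.ranked), "K": cfg.K},
            indent=2,
            sort_keys=True,
        )
        + "\n",
        encoding="utf-8",
    )
    return result


def build_lensed_lexicon(cfg: RunConfig) -> SentimentLexicon:
    base = read_lexicon(cfg.lexicon_path, dialect=cfg.lexicon_dialect)  # type: ignore[arg-type]
    merged = merge_recalibration(base, read_sme_table(cfg.sme_path)) if cfg.sme_path else base
    return apply_lens(merged, cfg.neutral_lo, cfg.neutral_hi)


def run_full(cfg: RunConfig) -> dict:
    """Score all notes, then run the platelet and treatment analyses.

    Writes scores CSV, strata summary JSON, post-hoc matrix CSV, timeline
    CSV, the day-21 word-shift tables, and a machine-readable report.
    Rerunning with an identical config reproduces every byte.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stops = _stops(cfg)
    lensed = build_lensed_lexicon(cfg)
    corpus = read_notes(cfg.notes_path)
    scores, n_unscorable = scoring.score_corpus(corpus, lensed, stops)

    with (out / "scores.csv").open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["note_id", "patient_id", "timestamp", "score", "n_scored_tokens"])
        for s in scores:
            writer.writerow([s.note_id, s.patient_id, s.timestamp.isoformat(), repr(s.score), s.n_scored_tokens])

    report: dict = {
        **_provenance(cfg),
        "n_notes": len(corpus),
        "n_scored": len(scores),
        "n_unscorable": n_unscorable,
        "lensed_lexicon_size": len(lensed),
    }

    if cfg.labs_path:
        labs, lab_rejects = comparative.read_labs(cfg.labs_path)
        strata = comparative.attach_notes_to_labs(scores, labs, window_days=cfg.window_days)
        balanced = comparative.balance_groups(strata, seed=cfg.seed)
        res = comparative.omnibus_and_posthoc(balanced, alpha=cfg.alpha)
        report["platelet"] = {
            "group_sizes": res.group_sizes,
            "group_means": res.group_means,
            "group_medians": res.group_medians,
            "all_normal": res.all_normal,
            "omnibus_test": res.omnibus_test,
            "statistic": res.statistic,
            "pvalue": res.pvalue,
            "posthoc_test": res.posthoc_test,
            "n_lab_rejects": len(lab_rejects),
        }
        if res.posthoc is not None:
            res.posthoc.to_csv(out / "posthoc_matrix.csv")

    if cfg.treatments_path and cfg.medication_matrix_path:
        matrix = comparative.read_medication_matrix(cfg.medication_matrix_path)
        med_records = _read_treatments(cfg.treatments_path)
        events, rx_rejects = comparative.map_medications(med_records, matrix)
        timeline = comparative.treatment_timeline(scores, events, horizon_days=cfg.horizon_days)
        with (out / "timeline.csv").open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["class", "day", "mean_score", "n_notes"])
            for cls in sorted(timeline):
                for day, (mean, n) in timeline[cls].items():
                    writer.writerow([cls, day, repr(mean), n])
        report["treatments"] = {
            "classes": sorted(timeline),
            "n_events": len(events),
            "n_rx_rejects": len(rx_rejects),
            "notes_per_class": {cls: sum(n for _, n in timeline[cls].values()) for cls in sorted(timeline)},
        }

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return report


def _read_treatments(path: str | Path) -> list[tuple[str, str, date]]:
    records = []
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                (str(row["patient_id"]), row["medication"], date.fromisoformat(row["start_date"]))
            )
    return records
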