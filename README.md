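# oncolex

Lexicon-based sentiment scoring of oncology clinical notes, with a
data-driven re-calibration of the lexicon to the clinical domain.

General-purpose happiness lexicons (such as labMT, ~10k words crowd-rated
1–9) misread clinical language: "positive" is rarely good news in an
oncology note. `oncolex` implements the full workflow for adapting such a
lexicon and validating the adapted instrument:

1. **Candidate selection** — find the words whose general-domain rating
   is least trustworthy in a note corpus, by combining (a) frequent
   non-lexicon words and (b) lexicon words whose *ambient sentiment*
   (mean score of the ±5 neighbouring tokens, pooled over occurrences)
   deviates most from their rating, ranked by frequency × |h − h_amb|
   and truncated to the top 200 — a ready-made expert survey sheet.
2. **Merge & lens** — overlay subject-matter-expert (SME) re-scores on
   the base list; exclude near-neutral (4, 6) original words from
   scoring while keeping every SME-scored word.
3. **Note scoring** — each note gets the frequency-weighted mean score
   of its lensed tokens, h = Σ f_w h_w / Σ f_w (no stemming; stop words
   excluded; unscored tokens ignored).
4. **Validation analyses** — note scores vs platelet-count strata
   (low < 160, normal 160–410, high > 410 ×10⁹/L; balanced groups;
   Shapiro + Anderson → ANOVA/Tukey or Kruskal–Wallis/Conover), daily
   score timelines for six weeks after treatment start, and word-shift
   graphs decomposing any two-corpus score difference into exact
   per-word contributions (h_w − H_ref)(p_w^comp − p_w^ref).

Because real oncology corpora are access-restricted, the package ships a
first-class synthetic-data generator that emulates the relevant structure
(Zipf vocabulary, overdispersed note streams, planted stratum shifts,
weekly treatment cycles, a day-21 side-effect dip, mixed-unit labs) with
known ground truth, so every stage is testable end to end.

## Worked example

Simulate a small cohort, score it, and compare scores across platelet
strata:

```sh
oncolex simulate --out-dir sim --seed 17 --patients 120 --notes-per-year 20
# wrote 5055 notes, 6215 labs to sim

oncolex score --notes sim/notes.jsonl --lexicon sim/lexicon.tsv --out scores.csv
# scored 5022 notes (33 unscorable) -> scores.csv

oncolex platelet --scores scores.csv --labs sim/labs.csv --out-dir plat --seed 17
# kruskal: stat=0.5892 p=0.745
```

The strata summary (`plat/strata_summary.json`) shows three balanced
groups of 469 notes with means 5.356 (low) / 5.365 (normal) / 5.332
(high). The Kruskal–Wallis p of 0.745 is the expected outcome at this
size: the generator plants stratum shifts of only 0.01–0.02 points, which
need tens of thousands of notes per group to resolve — the package's
power checks confirm detection at p < 0.001 with n = 5,000/group.

Selecting re-calibration candidates on the same corpus:

```sh
oncolex calibrate-select --notes sim/notes.jsonl --lexicon sim/lexicon.tsv \
    --out-dir calib --seed 17
# selected 200 words; coverage 0.378
head -4 calib/calibration_candidates.csv
# word,frequency,anchor_score,ambient_score,delta,rank_product,selected
# pain,2556,2.4,5.250166241080923,2.8501662410809234,7285.02491220284,1
# metastatic,1932,1.6,5.2027200623534275,3.6027200623534275,6960.455160466822,1
# good,2791,7.5,5.267619082810863,2.232380917189137,6230.575139874882,1
```

The top candidates are exactly the words a clinician would flag: extreme
words ("pain", "metastatic", "good") whose neighbourhood in notes is far
more neutral than their general-domain rating, i.e. the largest
frequency × mismatch products. The 200 selected words cover 37.8% of
non-stop note text. Other subcommands: `merge-lexicon`, `timeline`,
`wordshift`, `run-full` (config-driven end-to-end run).

## Layout

- `src/oncolex/lexicon.py` — lexicon I/O, SME merge, neutral-band lens
- `src/oncolex/textprep.py` — tokenizer, stop words, note I/O
- `src/oncolex/selection.py` — ambient sentiment and candidate ranking
- `src/oncolex/scoring.py` — note scores and daily means
- `src/oncolex/wordshift.py` — per-word shift decomposition
- `src/oncolex/comparative.py` — platelet strata, test decision tree,
  Conover–Iman post-hoc, treatment timelines
- `src/oncolex/synthetic_data.py` — ground-truth corpus generator
- `src/oncolex/pipeline.py`, `src/oncolex/cli.py` — orchestration + CLI

See `docs/methods.md` for the models, parameter semantics, synthetic-data
design and numerical choices.
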