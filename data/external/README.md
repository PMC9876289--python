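# External reference data (not redistributed)

Two published files are consumed from this directory when present; they are
not bundled because they are third-party data.

- `labmt.tsv` — the published labMT word list in its original tab-separated
  layout (`word, rank, happiness_average, happiness_sd, ...`). Read with
  `read_lexicon(path, dialect="labmt_full")`.
- `sme_rescoring.csv` — the oncology expert (SME) re-scoring table for the
  200 selected high-importance words, either as `word, rater_1..rater_k`
  per-rater columns or pre-aggregated `word, score, sd`. Read with
  `read_sme_table(path)`.

Tests that check summary statistics of these published tables fail with a
missing-file error until the files are placed here.
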