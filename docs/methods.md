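# Methods

`oncolex` implements a domain re-calibration workflow for 1–9 happiness
lexicons applied to oncology clinical notes, together with the downstream
analyses that such a re-calibrated instrument is validated with. This note
documents the models, the tunable parameters, the synthetic-data design,
and the numerical choices, in that order.

## The scoring instrument

A sentiment lexicon assigns each word $w$ a happiness score
$h_w \in [1, 9]$ (9 = happiest). The score of a note is the
frequency-weighted mean over its tokens:

$$ h_{\text{note}} \;=\; \frac{\sum_w f_w\, h_w}{\sum_w f_w}, $$

where $f_w$ counts occurrences of $w$ among the note's tokens after
stop-word removal, and the sum runs over words present in the *lensed*
lexicon. Tokens without a score are ignored entirely; notes with no
scorable token have no score and are excluded from aggregates (their count
is always reported). The unique-word formulation above is algebraically
identical to a per-token streaming mean — the test suite asserts this to
1e-12.

**Lens.** Near-neutral words carry little signal, so original-list words
with $4 < h_w < 6$ are excluded before scoring. The bounds are exclusive
(a word scored exactly 4.0 or 6.0 stays) and configurable. Words
re-scored or added by subject-matter experts (SMEs) are retained
regardless of score: in this domain their re-calibrated rating is
informative even when near-neutral (e.g. "positive" re-scored from 7.8
to ~5.6).

**Merging.** An SME table overlays the base list: every SME word enters
with the SME consensus score (mean of rater scores by default, median by
option), tagged `sme_rescored` if it overrides a base word and `sme_new`
otherwise. The merged size is exactly |base| + |new words|.

**Tokenization.** Lowercased maximal runs of letters/digits with internal
apostrophes; no stemming or lemmatization ("medications" ≠ "medication").
Digits stay inside tokens ("10mg") — such tokens simply never match the
lexicon. The packaged stop list is a standard English function-word list;
"no" and "not" are deliberately *not* on it, because negation carries
clinical sentiment. The active stop list is recorded in every run log so
scoring is auditable.

## Calibration-candidate selection

Two mechanisms, computed over a (sampled) note corpus, identify words
whose general-domain rating is least trustworthy in clinical text:

1. **Novel words** — tokens absent from the lexicon (and not stop words),
   counted by token frequency. Having no rating at all, they are assigned
   a mismatch $h^\delta = 1$.
2. **Ambient mismatch** — for each lexicon word ("anchor"), the *ambient
   sentiment* $h^{amb}$ is the mean lexicon score of the tokens within
   ±5 positions of each occurrence, pooled over all occurrences
   (an observation-pooled mean, not a mean of per-occurrence means).
   The mismatch is $h^\delta = |h - h^{amb}|$.

Candidates are ranked by $f \cdot h^\delta$ (token frequency × mismatch)
and truncated to the top $K = 200$. Ties break by frequency, then
alphabetically, so selection is deterministic. The coverage curve reports
the cumulative fraction of non-stop note text the top-$r$ words account
for; on default synthetic corpora the top 200 cover ~38%.

Window semantics: the window runs over raw token positions (stop words
occupy positions and contribute a score only if they are lexicon words);
windows never cross note boundaries and truncated windows are used as-is.
An anchor whose every occurrence has zero scored neighbours receives no
ambient score and drops out of ranking unless it qualifies as novel.

## Word-shift decomposition

With $p^{(c)}_w$ the relative frequency of $w$ among scorable tokens of
corpus $c$ and $H_{ref} = \sum_w p^{(ref)}_w h_w$ the token-pooled
reference mean, the difference in pooled means decomposes exactly:

$$ \delta_w = (h_w - H_{ref})\,\bigl(p^{(comp)}_w - p^{(ref)}_w\bigr),
\qquad \textstyle\sum_w \delta_w = H_{comp} - H_{ref}. $$

A word above the reference mean that is more common in the comparison
contributes positively. Shifts operate on token-pooled corpus means
(the decomposition is only exact there), whereas timelines use note-level
means; both are reported.

## Comparative analyses

**Platelet strata.** Lab values are converted to 10⁹/L through an
editable unit table (`/uL` × 0.001, `K/uL` × 1, …; unknown units go to a
rejects report, they are never fatal). Strata: low < 160, normal 160–410
(boundaries inclusive — "between 160 and 410" is read inclusively),
high > 410. A note joins stratum *s* if it falls within ±7 days of *any*
of its patient's tests stratified as *s*; note ids are unique within a
stratum, and a note near tests in two different strata counts in both
(a configurable exclusive mode drops such notes instead). Strata are then
balanced by seeded uniform downsampling to the smallest group.

**Test decision tree.** Each balanced stratum is checked with Shapiro–Wilk
(p > α) and Anderson–Darling (statistic below the 5% critical value for
the normal family). Only if *every* stratum passes both is a one-way
ANOVA with Tukey HSD used; otherwise a tie-corrected Kruskal–Wallis with
a Conover–Iman post-hoc on the pooled ranks. The post-hoc runs only when
the omnibus p < α. Conover–Iman statistic for groups $i, j$:

$$ t_{ij} = \frac{\bar R_i - \bar R_j}
  {\sqrt{S^2 \tfrac{N-1-H}{N-k}\left(\tfrac1{n_i}+\tfrac1{n_j}\right)}},
\qquad S^2 = \frac{\sum r^2 - N(N+1)^2/4}{N-1}, $$

referred to Student's t with $N-k$ df, two-sided. P-values are reported
unadjusted (Holm adjustment by flag). The tie-corrected H is computed
in-package (it is needed for the Conover scale factor anyway) and is
cross-checked against an independent implementation in the tests.

**Treatment timelines.** A medication→class matrix expands prescriptions
into treatment events; platinum agents map to both `platinum` and
`chemotherapy`, so one prescription can emit two events and a patient may
be counted in several classes. For each event, the patient's notes with
day offset 0–42 from the start date enter that class; per class and day
the *unweighted* mean of note scores is reported (each note counts once
regardless of length; a patient-weighted variant is available by flag).

## Synthetic data

No real clinical corpus can be redistributed, so every stage is exercised
on generated data with known ground truth.

- **Vocabulary**: Zipf weights $z_r \propto r^{-s}$ ($s = 1.05$) over
  5,000 words by default. The top ~30 ranks are stop words; a band of
  clinical content words sits at moderate ranks, some deliberately
  missing from the lexicon ("tab", "prn", "medication", …) to exercise
  the novel-word mechanism; the tail is synthetic tokens, a configurable
  fraction (0.6) of which carry scores.
- **Scores**: a mixture concentrated near the mean (N(µ, 0.6), 70%) with
  symmetric tails at µ±2.6 — the (4,6) lens removes a realistic mass
  (roughly half the lexicon).
- **Latent sentiment** per note: baseline 5.35 + platelet-stratum shift
  (defaults −0.01 low, 0 normal, −0.02 high — the order of the reported
  group differences) + a weekly sinusoid of amplitude 0.05 phase-locked
  to treatment start (troughs on visit days) + N(0, 0.30) note noise.
- **Realisation by exponential tilting**: token weights
  $z_w e^{\beta h_w}$ with β calibrated by inverse interpolation so that
  the expected note score *under the default lens and stop list* equals
  the latent value. This makes planted shifts directly recoverable: a
  planted 0.05 stratum shift reappears in empirical stratum means within
  ±0.01 at ~10⁴ notes/stratum. β is quantized to a 1024-point grid whose
  cumulative distributions are cached for bulk sampling.
- **Day-21 dip**: on day 21 of a treatment timeline, low-scored
  side-effect tokens ("nausea", "fatigue", "chemotherapy", "dose",
  "mouth") replace ordinary tokens with a probability solved so the
  expected note-score drop equals `dip_depth` (0.25 by default).
  Injected tokens are all lexicon-visible while only a fraction
  $P_s$ of base tokens are, so the replacement rate is
  $q = fP_s/(1-f(1-P_s))$ with $f = \text{dip\_depth}/(\mu - \bar h_{dip})$.
- **Note streams**: note counts and lengths are negative-binomial
  (clinical notes are overdispersed); default length 150 tokens. Note
  days are drawn over the observation window with tripled intensity on
  weekly visit days after treatment start. Labs are drawn inside each
  patient's stratum range, away from the 160/410 boundaries so planted
  labels are unambiguous, in a mix of reporting units including `/uL`.
- `notes_per_patient_year` defaults to 886 (the reported cohort mean);
  `SimConfig.desk()` is the preset used throughout the tests
  (200 patients, ~50 notes/patient, vocabulary 5,000) so the full
  pipeline runs in seconds.

**What the generator does not emulate** — and hence what passing tests do
*not* show about real data: actual clinical language (templates, section
headers, copy-forward text), note-type heterogeneity, within-patient
correlation of sentiment beyond the planted structure, platelet dynamics
over time (stratum is fixed per patient), informative timing of labs, and
site-specific unit dialects beyond the bundled table. Recovery results
demonstrate that the pipeline measures what was planted; they are not
evidence about clinical validity.

## Problem sizes used in the checks

Statistical checks fix their own sizes, chosen so the quantity under test
is comfortably identifiable:

- type-I control: 3×200 samples, 2,000 replicates; power: 3×5,000 with
  means spaced 0.02 (sd 0.30), 200 replicates;
- stratum-shift recovery: 300 patients, equal strata, long notes
  (600 tokens) and reduced note noise (0.10) so token-sampling error does
  not mask a 0.05 planted shift at the ±0.01 tolerance;
- weekly-cycle recovery: an all-treated cohort observed over a 120-day
  window (1,200 patients, >500 notes/day in the 43-day horizon), so the
  daily-mean standard error (~0.015) sits well below the 0.05 amplitude;
  periodicity is read off the pooled all-treatments series (every class
  shares the cycle) as the argmax over integer periods 2–14 of
  $|\sum_d (x_d - \bar x)\, e^{2\pi i d/p}|^2$.

## Numerical choices and degenerate inputs

- Selection ties break by (rank product desc, frequency desc, word asc).
- Identical groups under Kruskal–Wallis: H = 0, p = 1 (the tie-corrected
  formula is 0/0 when all observations are tied).
- Conover with all observations tied, or zero standard error: p = 1.
- Word-shift requires ≥1 scorable token per corpus; coverage requires a
  non-empty corpus after stop-word removal — both raise otherwise.
- Balancing with an empty stratum raises; the smallest stratum is passed
  through untouched, so its note order is stable.
- Anderson–Darling "pass" uses the 5% critical value of the normal
  family; Shapiro uses p > α with the same α as the omnibus (0.05).
- All randomness flows through `numpy.random.default_rng` seeded per
  stage; reruns with identical configs are byte-identical (report JSON
  has sorted keys and no timestamps).

## Known limitations

- The ambient window runs over raw token positions by default; corpora
  dominated by boilerplate stop-word runs will dilute ambient estimates.
- Conover p-values are unadjusted by default, mirroring the analysis this
  package reproduces; use `holm=True` for family-wise control.
- The unit table covers common platelet dialects only; site-specific
  units must be added to the editable CSV.
- Multi-word phrases, negation scope, sentence segmentation and
  de-identification are out of scope.
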