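"""Synthetic clinical corpora with known ground truth.

Real oncology note corpora are access-restricted, so every pipeline stage
is exercised on generated data whose true parameters are known. The
generator emulates the statistical features the analyses depend on:

* a Zipf-distributed vocabulary in which the most frequent tokens are
  English function words (stop words), a band of clinical content words
  (some deliberately absent from the lexicon, mirroring domain terms like
  "prn" or "medication" that a general-purpose word list misses), and a
  synthetic long tail;
* a 1-9 score lexicon concentrated near neutral with tails, so the
  (4, 6) lens removes a realistic mass of words;
* per-patient note streams over a two-year window, note lengths from a
  negative-binomial law (clinical note lengths are overdispersed);
* a latent per-note sentiment = baseline + platelet-stratum shift +
  weekly sinusoid phase-locked to treatment start + per-note noise,
  realised in the token stream by exponentially tilting the Zipf
  sampling weights by word score. The tilt is calibrated so that the
  expected note score *under the default lens and stop list* equals the
  latent value, which makes planted shifts directly recoverable;
* a day-21 "side-effect" dip realised by injecting low-scored
  treatment-related tokens into notes written on that day of a
  treatment timeline;
* platelet lab values consistent with the 160/410 strata in a mix of
  reporting units, and treatment prescriptions drawn from a bundled
  synthetic medication->class matrix.

All randomness flows through one numpy Generator per call, seeded from
SimConfig.seed: identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, datetime, timedelta

import numpy as np

from .lexicon import LexiconEntry, SentimentLexicon, apply_lens
from .textprep import NoteRecord, StopWordList, default_stopwords
from .comparative import LabResult

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimData",
    "generate_lexicon",
    "generate_corpus",
    "generate_labs_and_treatments",
    "simulate",
]

# clinical content words planted at moderately high Zipf ranks; the
# "novel" ones are kept out of the lexicon to exercise the non-lexicon
# frequency mechanism of the calibration selection
_CLINICAL_SCORED = {
    "patient": 5.2, "stable": 6.4, "well": 7.0, "today": 6.2, "care": 6.8,
    "support": 6.9, "pain": 2.4, "cancer": 1.8, "treatment": 4.2,
    "dose": 3.8, "nausea": 2.2, "fatigue": 2.6, "chemotherapy": 2.8,
    "discharge": 6.1, "negative": 2.6, "positive": 7.4, "lung": 4.4,
    "disease": 2.0, "metastatic": 1.6, "risk": 2.9, "pressure": 3.4,
    "fall": 3.0, "independent": 6.6, "activity": 6.3, "mouth": 4.3,
    "home": 7.1, "family": 7.2, "good": 7.5, "normal": 6.5, "severe": 2.1,
}
_CLINICAL_NOVEL = ("tab", "medication", "prn", "reviewed", "provider",
                   "mg", "po", "daily", "assessment", "plan")

# low-score lexicon words injected on the dip day of a treatment timeline
_DIP_TOKENS = ("nausea", "fatigue", "chemotherapy", "dose", "mouth")


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults follow the reported study conditions.

    ``notes_per_patient_year`` defaults to the reported cohort mean (886);
    the :meth:`desk` preset scales patient count and note volume down to
    a size the full pipeline handles in seconds while keeping the
    signal-to-noise structure.
    """

    n_patients: int = 200
    notes_per_patient_year: float = 886.0
    note_length_mean: float = 150.0
    note_length_dispersion: float = 2.0  # NB size parameter; var = m + m^2/r
    vocab_size: int = 5000
    zipf_exponent: float = 1.05
    lexicon_coverage: float = 0.6
    score_mean: float = 5.35
    baseline_sentiment: float = 5.35
    note_noise_sd: float = 0.30
    group_effects: tuple[tuple[str, float], ...] = (
        ("low", -0.010), ("normal", 0.0), ("high", -0.020),
    )
    group_probs: tuple[tuple[str, float], ...] = (
        ("low", 0.25), ("normal", 0.55), ("high", 0.20),
    )
    weekly_amplitude: float = 0.05
    dip_day: int = 21
    dip_depth: float = 0.25
    treated_fraction: float = 0.7
    lab_interval_days: float = 14.0
    window_days: int = 730
    start_date: date = date(2020, 1, 1)
    seed: int = 0

    @classmethod
    def desk(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Desk-scale preset: ~50 notes/patient, full pipeline in seconds."""
        base = cls(n_patients=200, notes_per_patient_year=25.0, seed=seed)
        return replace(base, **overrides)


@dataclass
class SimTruth:
    """Ground truth sufficient to predict every downstream statistic."""

    scores: dict[str, float]
    patient_stratum: dict[str, str]
    patient_treatment: dict[str, tuple[str, date]]  # medication, start
    note_latent: dict[str, float]
    note_day: dict[str, int]
    group_effects: dict[str, float]
    weekly_amplitude: float
    dip_day: int
    dip_depth: float
    dip_tokens: tuple[str, ...]
    novel_words: tuple[str, ...]
    zipf_exponent: float


@dataclass
class SimData:
    lexicon: SentimentLexicon
    notes: list[NoteRecord]
    labs: list[LabResult]
    med_records: list[tuple[str, str, date]]
    truth: SimTruth


# ------------------------------------------------------------------ vocab

def _build_vocab(config: SimConfig, rng: np.random.Generator, stops: StopWordList):
    """(words, scores-with-nan, zipf weights); clinical words at ranks 30-70."""
    n = config.vocab_size
    stop_pool = sorted(stops.words)
    n_stop = min(30, len(stop_pool), n // 10)
    stop_words = list(rng.permutation(stop_pool))[:n_stop]

    clinical = list(_CLINICAL_SCORED) + list(_CLINICAL_NOVEL)
    n_tail = n - n_stop - len(clinical)
    if n_tail < 0:
        raise ValueError(f"vocab_size {n} too small for the planted word sets")
    tail = [f"w{i:05d}" for i in range(n_tail)]

    words = stop_words + list(rng.permutation(clinical)) + tail
    scores = np.full(n, np.nan)

    # scored fraction of the tail, mixture concentrated near the mean
    tail_lo = n_stop + len(clinical)
    n_scored_tail = int(round(config.lexicon_coverage * n_tail))
    scored_idx = tail_lo + rng.choice(n_tail, size=n_scored_tail, replace=False)
    scores[scored_idx] = _score_mixture(n_scored_tail, config.score_mean, rng)
    for i, w in enumerate(words):
        if w in _CLINICAL_SCORED:
            scores[i] = _CLINICAL_SCORED[w]

    weights = (np.arange(1, n + 1, dtype=float)) ** (-config.zipf_exponent)
    weights /= weights.sum()
    return words, scores, weights


def _score_mixture(n: int, mean: float, rng: np.random.Generator) -> np.ndarray:
    """1-9 scores: 70% near-neutral core, 15%+15% symmetric tails."""
    comp = rng.choice(3, size=n, p=[0.70, 0.15, 0.15])
    mu = np.where(comp == 0, mean, np.where(comp == 1, mean - 2.6, mean + 2.6))
    sd = np.where(comp == 0, 0.6, 0.8)
    return np.clip(rng.normal(mu, sd), 1.0, 9.0)


def generate_lexicon(config: SimConfig) -> SentimentLexicon:
    """The scored subset of the synthetic vocabulary, as a lexicon."""
    if config.vocab_size < 10:
        raise ValueError("vocab_size must be >= 10")
    rng = np.random.default_rng(config.seed)
    stops = default_stopwords()
    words, scores, _ = _build_vocab(config, rng, stops)
    entries = [
        LexiconEntry(w, float(s))
        for w, s in zip(words, scores)
        if not np.isnan(s)
    ]
    return SentimentLexicon.from_entries(entries, name=f"synthetic(seed={config.seed})")


# ------------------------------------------------------------------ tilt

class _TiltedSampler:
    """Token sampler whose expected *measured* note score is calibrated.

    The base Zipf weights z are tilted to z * exp(beta * (h - 5)) for
    scored words. The measured note score only sees words that survive
    the lens and the stop list, so the calibration curve mu(beta) is the
    weighted mean score over exactly that subset; beta for a target mu is
    found by inverse interpolation and quantized to a fine grid whose
    cumulative distributions are precomputed for bulk sampling.
    """

    N_GRID = 1024
    BETA_MAX = 1.6

    def __init__(self, scores: np.ndarray, weights: np.ndarray, measurable: np.ndarray):
        self.weights = weights
        h = np.where(np.isnan(scores), 5.0, scores)
        self.h_centered = h - 5.0
        self.scored = ~np.isnan(scores)
        betas = np.linspace(-self.BETA_MAX, self.BETA_MAX, self.N_GRID)
        zm = weights[measurable]
        hm = scores[measurable]
        # mu(beta) over the measurable (lensed, non-stop, scored) subset
        tilts = np.exp(np.outer(betas, hm - 5.0)) * zm
        self.mu_grid = (tilts * hm).sum(axis=1) / tilts.sum(axis=1)
        self.beta_grid = betas
        self._cdf_cache: dict[int, np.ndarray] = {}

    def grid_index(self, mu_target: np.ndarray) -> np.ndarray:
        mu = np.clip(mu_target, self.mu_grid[0], self.mu_grid[-1])
        beta = np.interp(mu, self.mu_grid, self.beta_grid)
        return np.rint(
            (beta + self.BETA_MAX) / (2 * self.BETA_MAX) * (self.N_GRID - 1)
        ).astype(np.int64)

    def _cdf(self, gi: int) -> np.ndarray:
        cdf = self._cdf_cache.get(gi)
        if cdf is None:
            w = self.weights * np.exp(self.beta_grid[gi] * self.h_centered * self.scored)
            cdf = np.cumsum(w)
            cdf /= cdf[-1]
            self._cdf_cache[gi] = cdf
        return cdf

    def sample(self, gi: int, n: int, rng: np.random.Generator) -> np.ndarray:
        """n token indices from the tilted distribution at grid point gi."""
        return np.searchsorted(self._cdf(gi), rng.random(n), side="right")


# ------------------------------------------------------------------ corpus

def generate_corpus(
    config: SimConfig, truth_out: SimTruth | None = None
) -> tuple[list[NoteRecord], SimTruth]:
    """Per-patient note streams realising the planted sentiment structure.

    Returns (notes, truth); a SimTruth passed as `truth_out` is filled in
    place (and returned), so callers can thread one truth object through
    the individual generators.
    """
    rng = np.random.default_rng(config.seed)
    stops = default_stopwords()
    words, scores, weights = _build_vocab(config, rng, stops)
    word_arr = np.asarray(words, dtype=object)

    lensed = apply_lens(
        SentimentLexicon.from_entries(
            LexiconEntry(w, float(s)) for w, s in zip(words, scores) if not np.isnan(s)
        )
    )
    measurable = np.array(
        [(w in lensed) and (w not in stops.words) for w in words], dtype=bool
    )
    sampler = _TiltedSampler(scores, weights, measurable)

    group_probs = dict(config.group_probs)
    group_effects = dict(config.group_effects)
    strata = list(group_probs)
    p = np.array([group_probs[s] for s in strata])
    p /= p.sum()

    meds = _medication_pool()
    truth = truth_out if truth_out is not None else _empty_truth(config)
    truth.group_effects = group_effects
    truth.weekly_amplitude = config.weekly_amplitude
    truth.dip_day, truth.dip_depth = config.dip_day, config.dip_depth
    truth.dip_tokens = _DIP_TOKENS
    truth.novel_words = _CLINICAL_NOVEL
    truth.zipf_exponent = config.zipf_exponent
    truth.scores = {w: float(s) for w, s in zip(words, scores) if not np.isnan(s)}

    dip_ids = np.array([words.index(t) for t in _DIP_TOKENS])
    dip_scores = scores[dip_ids]
    # Injected tokens are all lexicon-visible while only a fraction P_s of
    # base tokens are, so a per-token replacement probability q yields an
    # injected fraction q / (q + (1-q) P_s) among *scored* tokens. Solve
    # for q so the expected dip-day score drop equals dip_depth.
    p_scored = float(weights[measurable].sum())
    frac = config.dip_depth / max(0.5, config.baseline_sentiment - float(np.mean(dip_scores)))
    frac = min(frac, 0.95)
    q_dip = frac * p_scored / max(1e-9, 1.0 - frac * (1.0 - p_scored))

    notes_meta: list[tuple[str, str, datetime, float, bool]] = []
    n_years = config.window_days / 365.0
    for i in range(config.n_patients):
        pid = f"p{i:04d}"
        stratum = strata[rng.choice(len(strata), p=p)]
        truth.patient_stratum[pid] = stratum
        treated = rng.random() < config.treated_fraction
        t_start: int | None = None
        if treated:
            medication = meds[rng.integers(len(meds))]
            t_start = int(rng.integers(30, max(31, config.window_days - config.dip_day - 42)))
            truth.patient_treatment[pid] = (
                medication,
                config.start_date + timedelta(days=t_start),
            )
        mean_notes = config.notes_per_patient_year * n_years
        r = config.note_length_dispersion
        n_notes = max(1, int(rng.negative_binomial(r, r / (r + mean_notes))))
        day_w = np.ones(config.window_days)
        if t_start is not None:
            visit_days = t_start + 7 * np.arange(0, 7)
            visit_days = visit_days[visit_days < config.window_days]
            day_w[visit_days] += 2.0  # weekly treatment visits generate notes
        day_w /= day_w.sum()
        days = rng.choice(config.window_days, size=n_notes, p=day_w)
        for j, d in enumerate(sorted(days.tolist())):
            latent = config.baseline_sentiment + group_effects[stratum]
            on_dip = False
            if t_start is not None and d >= t_start:
                offset = d - t_start
                if offset <= 42:
                    latent -= config.weekly_amplitude * np.cos(2 * np.pi * offset / 7.0)
                on_dip = offset == config.dip_day
            latent += rng.normal(0.0, config.note_noise_sd)
            ts = config.start_date + timedelta(days=int(d))
            when = datetime(ts.year, ts.month, ts.day, int(rng.integers(8, 18)), int(rng.integers(60)))
            nid = f"{pid}-n{j:05d}"
            notes_meta.append((nid, pid, when, latent, on_dip))
            truth.note_latent[nid] = float(latent)
            truth.note_day[nid] = int(d)

    # bulk token sampling, grouped by tilt grid index
    lengths = np.maximum(
        5,
        rng.negative_binomial(
            config.note_length_dispersion,
            config.note_length_dispersion
            / (config.note_length_dispersion + config.note_length_mean),
            size=len(notes_meta),
        ),
    )
    latents = np.array([m[3] for m in notes_meta])
    gis = sampler.grid_index(latents)
    token_lists: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * len(notes_meta)
    order = np.argsort(gis, kind="stable")
    pos = 0
    while pos < len(order):
        end = pos
        gi = gis[order[pos]]
        while end < len(order) and gis[order[end]] == gi:
            end += 1
        block = order[pos:end]
        total = int(lengths[block].sum())
        drawn = sampler.sample(int(gi), total, rng)
        offs = np.concatenate(([0], np.cumsum(lengths[block])))
        for b, idx in enumerate(block):
            token_lists[idx] = drawn[offs[b] : offs[b + 1]]
        pos = end

    notes: list[NoteRecord] = []
    for (nid, pid, when, _latent, on_dip), toks in zip(notes_meta, token_lists):
        if on_dip and q_dip > 0:
            mask = rng.random(len(toks)) < q_dip
            toks = toks.copy()
            toks[mask] = dip_ids[rng.integers(len(dip_ids), size=int(mask.sum()))]
        token_tuple = tuple(word_arr[toks])
        notes.append(NoteRecord(nid, pid, when, " ".join(token_tuple), token_tuple))
    return notes, truth


def _empty_truth(config: SimConfig) -> SimTruth:
    return SimTruth(
        scores={},
        patient_stratum={},
        patient_treatment={},
        note_latent={},
        note_day={},
        group_effects=dict(config.group_effects),
        weekly_amplitude=config.weekly_amplitude,
        dip_day=config.dip_day,
        dip_depth=config.dip_depth,
        dip_tokens=_DIP_TOKENS,
        novel_words=_CLINICAL_NOVEL,
        zipf_exponent=config.zipf_exponent,
    )


def _medication_pool() -> list[str]:
    from .comparative import read_medication_matrix
    from importlib import resources

    path = resources.files("oncolex.data").joinpath("medication_matrix_synthetic.csv")
    with resources.as_file(path) as p:
        return sorted(read_medication_matrix(p))


# ---------------------------------------------------------- labs & events

_STRATUM_RANGES = {"low": (60.0, 155.0), "normal": (170.0, 400.0), "high": (420.0, 650.0)}
_UNIT_CHOICES = ("10^9/L", "K/uL", "/uL", "K/cmm")


def generate_labs_and_treatments(
    config: SimConfig, truth: SimTruth
) -> tuple[list[LabResult], list[tuple[str, str, date]]]:
    """Platelet labs consistent with each patient's stratum, plus rx records.

    Values are drawn inside the stratum's range (away from the 160/410
    boundaries so the planted label is unambiguous) and reported in a mix
    of units — including /uL, which exercises the x0.001 conversion.
    """
    rng = np.random.default_rng(config.seed + 1)
    labs: list[LabResult] = []
    for pid, stratum in sorted(truth.patient_stratum.items()):
        lo, hi = _STRATUM_RANGES[stratum]
        day = float(rng.exponential(config.lab_interval_days))
        while day < config.window_days:
            value = float(rng.uniform(lo, hi))
            unit = _UNIT_CHOICES[rng.integers(len(_UNIT_CHOICES))]
            if unit == "/uL":
                value *= 1000.0
            d = config.start_date + timedelta(days=int(day))
            labs.append(LabResult(pid, datetime(d.year, d.month, d.day, 9, 0), value, unit))
            day += float(rng.exponential(config.lab_interval_days))
    med_records = [
        (pid, med, start) for pid, (med, start) in sorted(truth.patient_treatment.items())
    ]
    return labs, med_records


def simulate(config: SimConfig) -> SimData:
    """Full bundle: lexicon, notes, labs, prescriptions and ground truth."""
    notes, truth = generate_corpus(config)
    lexicon = SentimentLexicon.from_entries(
        (LexiconEntry(w, s) for w, s in sorted(truth.scores.items())),
        name=f"synthetic(seed={config.seed})",
    )
    labs, med_records = generate_labs_and_treatments(config, truth)
    return SimData(lexicon, notes, labs, med_records, truth)
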