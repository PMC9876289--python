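"""Comparative validation of note sentiment against labs and treatments.

Platelet branch: lab values are normalized to 10^9/L, stratified into
low (< 160), normal (160-410, bounds inclusive) and high (> 410); notes
within +/- 7 days of a test join that test's stratum (unique note ids per
stratum); strata are balanced by seeded downsampling to the smallest
group; normality (Shapiro-Wilk and Anderson-Darling at the 5% critical
value) then selects a one-way ANOVA with Tukey post-hoc when every group
looks normal, and otherwise a tie-corrected Kruskal-Wallis with a
Conover-Iman post-hoc on the pooled ranks. The post-hoc only runs when
the omnibus test is significant.

Treatment branch: medications map to treatment classes (platinum agents
are also chemotherapy, so one prescription can emit several events); a
patient's notes in the six weeks from a treatment start are aggregated
into a per-class daily mean-score timeline.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date, datetime
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import NoteScore

__all__ = [
    "LabResult",
    "PlateletStratum",
    "TreatmentEvent",
    "StrataResult",
    "default_unit_factors",
    "read_unit_factors",
    "normalize_platelet_units",
    "stratify_platelets",
    "attach_notes_to_labs",
    "balance_groups",
    "omnibus_and_posthoc",
    "kruskal_wallis",
    "conover_posthoc",
    "map_medications",
    "read_medication_matrix",
    "treatment_timeline",
    "read_labs",
]

STRATA = ("low", "normal", "high")
TREATMENT_CLASSES = ("chemotherapy", "platinum", "targeted", "checkpoint")

LOW_THRESHOLD = 160.0  # 10^9/L
HIGH_THRESHOLD = 410.0


@dataclass(frozen=True)
class LabResult:
    patient_id: str
    timestamp: datetime
    value: float
    unit: str


@dataclass
class PlateletStratum:
    label: str
    note_scores: list[NoteScore] = field(default_factory=list)

    def values(self) -> np.ndarray:
        return np.asarray([s.score for s in self.note_scores], dtype=float)


@dataclass(frozen=True)
class TreatmentEvent:
    patient_id: str
    treatment_class: str
    start_date: date


@dataclass
class StrataResult:
    group_sizes: dict[str, int]
    normality: dict[str, dict[str, float | bool]]
    all_normal: bool
    omnibus_test: str
    statistic: float
    pvalue: float
    posthoc_test: str | None
    posthoc: pd.DataFrame | None
    group_means: dict[str, float]
    group_medians: dict[str, float]


# ---------------------------------------------------------------- units

def default_unit_factors() -> dict[str, float]:
    """Multiplicative factors taking a platelet value to 10^9/L."""
    path = resources.files("oncolex.data").joinpath("platelet_units.csv")
    with path.open(encoding="utf-8") as fh:  # type: ignore[call-arg]
        return {row["unit"].strip(): float(row["factor"]) for row in csv.DictReader(fh)}


def read_unit_factors(path: str | Path) -> dict[str, float]:
    """Site-editable unit table: CSV with columns ``unit, factor``."""
    with Path(path).open(encoding="utf-8", newline="") as fh:
        return {row["unit"].strip(): float(row["factor"]) for row in csv.DictReader(fh)}


def normalize_platelet_units(
    result: LabResult, factors: Mapping[str, float] | None = None
) -> float:
    """Convert a lab value to 10^9/L; unknown units raise KeyError."""
    factors = factors if factors is not None else default_unit_factors()
    unit = result.unit.strip()
    if unit not in factors:
        raise KeyError(f"unrecognized platelet unit {result.unit!r}")
    return result.value * factors[unit]


def stratify_platelets(value: float) -> str:
    """low / normal / high per the 160 and 410 (10^9/L) thresholds.

    Boundary values 160 and 410 are normal (inclusive normal range).
    """
    if value < 0:
        raise ValueError(f"negative platelet value {value}")
    if value < LOW_THRESHOLD:
        return "low"
    if value <= HIGH_THRESHOLD:
        return "normal"
    return "high"


def read_labs(
    path: str | Path, factors: Mapping[str, float] | None = None
) -> tuple[list[LabResult], list[dict]]:
    """Read a labs CSV (patient_id, timestamp, value, unit).

    Returns (accepted records, rejects report). Records with unknown units
    or negative values are rejected with a reason, not fatal.
    """
    factors = factors if factors is not None else default_unit_factors()
    accepted: list[LabResult] = []
    rejects: list[dict] = []
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            rec = LabResult(
                str(row["patient_id"]),
                datetime.fromisoformat(row["timestamp"]),
                float(row["value"]),
                row["unit"],
            )
            if rec.unit.strip() not in factors:
                rejects.append({"patient_id": rec.patient_id, "unit": rec.unit, "reason": "unknown unit"})
            elif rec.value < 0:
                rejects.append({"patient_id": rec.patient_id, "value": rec.value, "reason": "negative value"})
            else:
                accepted.append(rec)
    return accepted, rejects


# ---------------------------------------------------------------- strata

def attach_notes_to_labs(
    scores: Sequence[NoteScore],
    labs: Sequence[LabResult],
    window_days: int = 7,
    factors: Mapping[str, float] | None = None,
    ambiguous: Literal["both", "drop"] = "both",
) -> list[PlateletStratum]:
    """Assign note scores to platelet strata via a +/- window interval join.

    A note joins stratum s when it lies within `window_days` days of ANY
    of its patient's tests stratified as s; each note id appears at most
    once per stratum. With ``ambiguous="drop"``, notes near tests in two
    different strata are discarded instead of counted in both.
    """
    factors = factors if factors is not None else default_unit_factors()
    tests_by_patient: dict[str, list[tuple[datetime, str]]] = {}
    for lab in labs:
        value = normalize_platelet_units(lab, factors)
        tests_by_patient.setdefault(lab.patient_id, []).append((lab.timestamp, stratify_platelets(value)))

    window_secs = window_days * 86400.0
    membership: dict[str, dict[str, NoteScore]] = {s: {} for s in STRATA}
    for score in scores:
        if not score.defined:
            continue
        hit: set[str] = set()
        for ts, stratum in tests_by_patient.get(score.patient_id, ()):
            if abs((score.timestamp - ts).total_seconds()) <= window_secs:
                hit.add(stratum)
        if ambiguous == "drop" and len(hit) > 1:
            continue
        for stratum in hit:
            membership[stratum].setdefault(score.note_id, score)
    return [PlateletStratum(s, list(membership[s].values())) for s in STRATA]


def balance_groups(strata: Sequence[PlateletStratum], seed: int) -> list[PlateletStratum]:
    """Downsample every stratum (uniform, seeded) to the smallest stratum size."""
    if len(strata) < 2:
        raise ValueError("need at least 2 strata")
    sizes = [len(s.note_scores) for s in strata]
    if min(sizes) == 0:
        raise ValueError("cannot balance: empty stratum")
    target = min(sizes)
    rng = np.random.default_rng(seed)
    out: list[PlateletStratum] = []
    for s in strata:
        if len(s.note_scores) == target:
            out.append(PlateletStratum(s.label, list(s.note_scores)))
        else:
            idx = rng.choice(len(s.note_scores), size=target, replace=False)
            out.append(PlateletStratum(s.label, [s.note_scores[i] for i in sorted(idx)]))
    return out


# ---------------------------------------------------------------- tests

def _normality(x: np.ndarray, alpha: float) -> dict[str, float | bool]:
    import warnings

    with warnings.catch_warnings():
        # scipy warns that Shapiro p-values are approximate for n > 5000;
        # at such sizes normality is rejected for trivial deviations anyway
        # (expected here), and the branch decision is unaffected.
        warnings.simplefilter("ignore", UserWarning)
        shapiro = stats.shapiro(x)
        # scipy >= 1.17 announces a future p-value API for anderson(); the
        # decision here uses the classical 5% critical value either way
        warnings.simplefilter("ignore", FutureWarning)
        anderson = stats.anderson(x, dist="norm")
    crit_5 = float(anderson.critical_values[list(anderson.significance_level).index(5.0)])
    return {
        "shapiro_stat": float(shapiro.statistic),
        "shapiro_p": float(shapiro.pvalue),
        "anderson_stat": float(anderson.statistic),
        "anderson_crit_5pct": crit_5,
        "normal": bool(shapiro.pvalue > alpha and anderson.statistic < crit_5),
    }


def conover_posthoc(groups: Sequence[np.ndarray], labels: Sequence[str]) -> pd.DataFrame:
    """Conover-Iman pairwise comparisons on the pooled Kruskal-Wallis ranks.

    With pooled mid-ranks r over all N observations in k groups, group mean
    ranks Rbar_i, the tie-corrected KW statistic H and
    S^2 = (sum r^2 - N (N+1)^2 / 4) / (N - 1), the pairwise statistic

        t_ij = (Rbar_i - Rbar_j) / sqrt(S^2 (N-1-H)/(N-k) (1/n_i + 1/n_j))

    is referred to Student's t with N - k degrees of freedom (two-sided).
    P-values are reported unadjusted.
    """
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    N = int(ns.sum())
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    bounds = np.concatenate(([0], np.cumsum(ns)))
    mean_ranks = np.array([ranks[bounds[i] : bounds[i + 1]].mean() for i in range(k)])

    H = _kruskal_statistic(ranks, bounds)
    s2 = (np.sum(ranks**2) - N * (N + 1) ** 2 / 4.0) / (N - 1)
    if s2 <= 0 or N - k <= 0:  # all observations tied, or degenerate sizes
        pmat = np.ones((k, k))
    else:
        factor = s2 * max(N - 1 - H, 0.0) / (N - k)
        pmat = np.ones((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(factor * (1.0 / ns[i] + 1.0 / ns[j]))
                if se == 0:
                    p = 1.0
                else:
                    t = (mean_ranks[i] - mean_ranks[j]) / se
                    p = 2.0 * stats.t.sf(abs(t), N - k)
                pmat[i, j] = pmat[j, i] = min(p, 1.0)
    return pd.DataFrame(pmat, index=list(labels), columns=list(labels))


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value (k-1 df)."""
    ns = np.array([len(g) for g in groups])
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = stats.rankdata(pooled)
    bounds = np.concatenate(([0], np.cumsum(ns)))
    h = _kruskal_statistic(ranks, bounds)
    return h, float(stats.chi2.sf(h, len(groups) - 1))


def _kruskal_statistic(ranks: np.ndarray, bounds: np.ndarray) -> float:
    """Tie-corrected KW H from pooled mid-ranks and group boundaries."""
    N = len(ranks)
    h = 0.0
    for i in range(len(bounds) - 1):
        g = ranks[bounds[i] : bounds[i + 1]]
        h += g.sum() ** 2 / len(g)
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    _, counts = np.unique(ranks, return_counts=True)
    ties = np.sum(counts**3 - counts)
    correction = 1.0 - ties / (N**3 - N)
    return h / correction if correction > 0 else 0.0


def omnibus_and_posthoc(
    strata: Sequence[PlateletStratum],
    alpha: float = 0.05,
    holm: bool = False,
) -> StrataResult:
    """Normality-gated omnibus comparison with conditional post-hoc.

    ANOVA + Tukey when every stratum passes both Shapiro (p > alpha) and
    Anderson-Darling (statistic below the 5% critical value); otherwise
    Kruskal-Wallis + Conover. The post-hoc matrix is None when the
    omnibus p-value is >= alpha.
    """
    if len(strata) < 2:
        raise ValueError("need at least 2 strata")
    groups = [s.values() for s in strata]
    labels = [s.label for s in strata]
    if any(len(g) < 3 for g in groups):
        raise ValueError("each stratum needs at least 3 scores")

    normality = {lab: _normality(g, alpha) for lab, g in zip(labels, groups)}
    all_normal = all(n["normal"] for n in normality.values())

    posthoc: pd.DataFrame | None = None
    posthoc_test: str | None = None
    if all_normal:
        omnibus = "anova"
        stat, p = stats.f_oneway(*groups)
        if p < alpha:
            posthoc_test = "tukey"
            res = stats.tukey_hsd(*groups)
            pmat = np.ones((len(groups), len(groups)))
            for i in range(len(groups)):
                for j in range(len(groups)):
                    if i != j:
                        pmat[i, j] = res.pvalue[i, j]
            posthoc = pd.DataFrame(pmat, index=labels, columns=labels)
    else:
        omnibus = "kruskal"
        if all(np.array_equal(groups[0], g) for g in groups[1:]):
            stat, p = 0.0, 1.0  # identical groups: no evidence of difference
        else:
            stat, p = kruskal_wallis(groups)
        if p < alpha:
            posthoc_test = "conover"
            posthoc = conover_posthoc(groups, labels)
    if holm and posthoc is not None:
        posthoc = _holm_adjust(posthoc)

    return StrataResult(
        group_sizes={lab: len(g) for lab, g in zip(labels, groups)},
        normality=normality,
        all_normal=all_normal,
        omnibus_test=omnibus,
        statistic=float(stat),
        pvalue=float(p),
        posthoc_test=posthoc_test,
        posthoc=posthoc,
        group_means={lab: float(np.mean(g)) for lab, g in zip(labels, groups)},
        group_medians={lab: float(np.median(g)) for lab, g in zip(labels, groups)},
    )


def _holm_adjust(pmat: pd.DataFrame) -> pd.DataFrame:
    """Holm step-down adjustment of the upper-triangle p-values."""
    labels = list(pmat.index)
    pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    raw = np.array([pmat.iat[i, j] for i, j in pairs])
    order = np.argsort(raw)
    m = len(raw)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * raw[idx])
        adj[idx] = min(running, 1.0)
    out = pmat.copy()
    for (i, j), p in zip(pairs, adj):
        out.iat[i, j] = out.iat[j, i] = p
    return out


# ------------------------------------------------------------- treatments

def read_medication_matrix(path: str | Path) -> dict[str, frozenset[str]]:
    """Medication -> treatment-class mapping CSV.

    Columns: ``medication, chemotherapy, platinum, targeted, checkpoint``
    with 0/1 flags; a platinum agent is flagged for both platinum and
    chemotherapy.
    """
    matrix: dict[str, frozenset[str]] = {}
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            med = row["medication"].strip().lower()
            classes = frozenset(c for c in TREATMENT_CLASSES if row.get(c, "0").strip() == "1")
            matrix[med] = classes
    return matrix


def map_medications(
    med_records: Sequence[tuple[str, str, date]],
    matrix: Mapping[str, frozenset[str] | set[str]],
) -> tuple[list[TreatmentEvent], list[dict]]:
    """Expand (patient, medication, start) records into per-class events.

    A medication mapping to several classes emits one event per class;
    duplicate (patient, class, start) combinations collapse. Unknown
    medications go to the rejects report.
    """
    events: set[TreatmentEvent] = set()
    rejects: list[dict] = []
    for patient_id, medication, start in med_records:
        med = medication.strip().lower()
        classes = matrix.get(med)
        if classes is None:
            rejects.append({"patient_id": patient_id, "medication": medication, "reason": "unknown medication"})
            continue
        for cls in classes:
            events.add(TreatmentEvent(patient_id, cls, start))
    ordered = sorted(events, key=lambda e: (e.patient_id, e.treatment_class, e.start_date))
    return ordered, rejects


def treatment_timeline(
    scores: Sequence[NoteScore],
    events: Sequence[TreatmentEvent],
    horizon_days: int = 42,
) -> dict[str, dict[int, tuple[float, int]]]:
    """Per-class daily mean note score for the horizon after treatment start.

    For each event, the patient's notes with 0 <= day <= horizon_days
    (day = calendar days since the start date, day 0 = start day) join the
    event's class at their offset; a note may feed several classes or
    events but counts once per (class, day). Classes with no notes are
    omitted.
    """
    by_patient: dict[str, list[NoteScore]] = {}
    for s in scores:
        if s.defined:
            by_patient.setdefault(s.patient_id, []).append(s)

    per_class: dict[str, dict[tuple[int, str], NoteScore]] = {}
    for ev in events:
        for s in by_patient.get(ev.patient_id, ()):
            day = (s.timestamp.date() - ev.start_date).days
            if 0 <= day <= horizon_days:
                per_class.setdefault(ev.treatment_class, {})[(day, s.note_id)] = s

    out: dict[str, dict[int, tuple[float, int]]] = {}
    for cls, members in per_class.items():
        sums: dict[int, float] = {}
        counts: dict[int, int] = {}
        for (day, _), s in members.items():
            sums[day] = sums.get(day, 0.0) + float(s.score)  # defined by construction
            counts[day] = counts.get(day, 0) + 1
        out[cls] = {d: (sums[d] / counts[d], counts[d]) for d in sorted(sums)}
    return out
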