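"""Platelet strata, normality-gated testing, Conover post-hoc, timelines."""

from __future__ import annotations

from datetime import date, datetime

import numpy as np
import pytest
from scipy import stats

from oncolex.comparative import (
    LabResult,
    PlateletStratum,
    TreatmentEvent,
    attach_notes_to_labs,
    balance_groups,
    conover_posthoc,
    default_unit_factors,
    map_medications,
    normalize_platelet_units,
    omnibus_and_posthoc,
    stratify_platelets,
    treatment_timeline,
)
from oncolex.comparative import _kruskal_statistic
from oncolex.scoring import NoteScore


def ns(note_id, patient, day, score=5.0, hour=12):
    from datetime import timedelta

    return NoteScore(note_id, patient, datetime(2020, 1, 1, hour) + timedelta(days=day), score, 10)


class TestUnits:
    def test_identity_factor(self):
        assert normalize_platelet_units(LabResult("p", datetime(2020, 1, 1), 250, "K/uL")) == 250

    def test_per_microliter_conversion(self):
        assert normalize_platelet_units(LabResult("p", datetime(2020, 1, 1), 250000, "/uL")) == 250

    def test_unknown_unit_rejected(self):
        with pytest.raises(KeyError):
            normalize_platelet_units(LabResult("p", datetime(2020, 1, 1), 250, "banana"))

    def test_table_is_editable(self, tmp_path):
        from oncolex.comparative import read_unit_factors

        p = tmp_path / "units.csv"
        p.write_text("unit,factor\nGpt/L,1\n")
        assert read_unit_factors(p) == {"Gpt/L": 1.0}

    def test_default_table_contents(self):
        factors = default_unit_factors()
        assert factors["10^9/L"] == 1.0 and factors["/uL"] == 0.001


class TestStratify:
    @pytest.mark.parametrize(
        "value,label",
        [(150, "low"), (300, "normal"), (500, "high"), (160, "normal"), (410, "normal")],
    )
    def test_thresholds(self, value, label):
        assert stratify_platelets(value) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            stratify_platelets(-1)


class TestAttach:
    def lab(self, patient, day, value, unit="10^9/L"):
        return LabResult(patient, datetime(2020, 1, 1 + day, 9), value, unit)

    def strata_dict(self, strata):
        return {s.label: sorted(x.note_id for x in s.note_scores) for s in strata}

    def test_note_inside_window(self):
        got = self.strata_dict(attach_notes_to_labs([ns("n1", "p1", 3)], [self.lab("p1", 0, 100)]))
        assert got["low"] == ["n1"]

    def test_note_outside_window(self):
        got = self.strata_dict(attach_notes_to_labs([ns("n1", "p1", 8)], [self.lab("p1", 0, 100)]))
        assert got == {"low": [], "normal": [], "high": []}

    def test_cross_stratum_duplication_and_within_stratum_dedup(self):
        labs = [
            self.lab("p1", 0, 100),  # low
            self.lab("p1", 4, 100),  # low again
            self.lab("p1", 6, 500),  # high
        ]
        got = self.strata_dict(attach_notes_to_labs([ns("n1", "p1", 2)], labs))
        assert got["low"] == ["n1"] and got["high"] == ["n1"]

    def test_ambiguous_drop_mode(self):
        labs = [self.lab("p1", 0, 100), self.lab("p1", 6, 500)]
        got = self.strata_dict(
            attach_notes_to_labs([ns("n1", "p1", 2)], labs, ambiguous="drop")
        )
        assert got["low"] == [] and got["high"] == []

    def test_interval_join_oracle(self):
        rng = np.random.default_rng(0)
        labs, notes = [], []
        for p in ("p1", "p2", "p3"):
            for i in range(rng.integers(1, 5)):
                labs.append(self.lab(p, int(rng.integers(0, 30)), float(rng.choice([100, 300, 500]))))
            for i in range(rng.integers(1, 15)):
                notes.append(ns(f"{p}-n{i}", p, int(rng.integers(0, 30)), hour=9))
        got = self.strata_dict(attach_notes_to_labs(notes, labs))
        want = {"low": set(), "normal": set(), "high": set()}
        for s in notes:
            for lab in labs:
                if (
                    lab.patient_id == s.patient_id
                    and abs((s.timestamp - lab.timestamp).total_seconds()) <= 7 * 86400
                ):
                    want[stratify_platelets(lab.value)].add(s.note_id)
        assert {k: set(v) for k, v in got.items()} == want


class TestBalance:
    def mk(self, sizes):
        return [
            PlateletStratum(lab, [ns(f"{lab}{i}", "p", 0, 5.0) for i in range(n)])
            for lab, n in zip(("low", "normal", "high"), sizes)
        ]

    def test_downsample_to_minimum(self):
        balanced = balance_groups(self.mk((10, 7, 9)), seed=1)
        assert [len(s.note_scores) for s in balanced] == [7, 7, 7]

    def test_already_equal_unchanged(self):
        strata = self.mk((5, 5, 5))
        balanced = balance_groups(strata, seed=1)
        assert [s.note_scores for s in balanced] == [s.note_scores for s in strata]

    def test_seed_reproducibility(self):
        a = balance_groups(self.mk((20, 7, 9)), seed=3)
        b = balance_groups(self.mk((20, 7, 9)), seed=3)
        c = balance_groups(self.mk((20, 7, 9)), seed=4)
        ids = lambda st: [[x.note_id for x in s.note_scores] for s in st]
        assert ids(a) == ids(b)
        assert ids(a) != ids(c)

    def test_membership_preserved(self):
        strata = self.mk((20, 7, 9))
        balanced = balance_groups(strata, seed=0)
        for orig, bal in zip(strata, balanced):
            orig_ids = {x.note_id for x in orig.note_scores}
            assert all(x.note_id in orig_ids for x in bal.note_scores)

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            balance_groups(self.mk((0, 5, 5)), seed=1)


class TestKruskalConover:
    def test_kruskal_internal_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            groups = [rng.choice(np.arange(0, 10, 0.5), size=rng.integers(5, 20)) for _ in range(3)]
            pooled = np.concatenate(groups)
            ranks = stats.rankdata(pooled)
            bounds = np.concatenate(([0], np.cumsum([len(g) for g in groups])))
            want = stats.kruskal(*groups)
            assert _kruskal_statistic(ranks, bounds) == pytest.approx(want.statistic, rel=1e-12)
            from oncolex.comparative import kruskal_wallis

            h, p = kruskal_wallis(groups)
            assert h == pytest.approx(want.statistic, rel=1e-12)
            assert p == pytest.approx(want.pvalue, rel=1e-9)

    def test_conover_frozen_hand_computation(self):
        # no-ties fixture with ranks 1..9 by group: mean ranks 2/5/8,
        # H = 7.2, S^2 = 7.5, scale = S^2 (N-1-H)/(N-k) = 1, se = sqrt(2/3),
        # t = {-3.674234, -7.348469}, df = 6
        groups = [np.array([1.2, 3.4, 2.2]), np.array([5.1, 4.0, 6.3]), np.array([9.0, 8.2, 7.5])]
        pmat = conover_posthoc(groups, ["a", "b", "c"])
        assert pmat.loc["a", "b"] == pytest.approx(0.010401720935464, rel=1e-9)
        assert pmat.loc["b", "c"] == pytest.approx(0.010401720935464, rel=1e-9)
        assert pmat.loc["a", "c"] == pytest.approx(0.000324974679271, rel=1e-9)

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(size=20), rng.normal(size=20), rng.normal(0.5, size=20)]
        pmat = conover_posthoc(groups, ["x", "y", "z"])
        assert np.allclose(pmat.values, pmat.values.T)
        assert np.allclose(np.diag(pmat.values), 1.0)

    def test_null_pairwise_rejection_rate(self):
        # under identical distributions, Conover rejections at alpha
        # should occur at about alpha per pair (run unconditionally here)
        rng = np.random.default_rng(12)
        alpha, hits, total = 0.05, 0, 0
        for _ in range(400):
            groups = [rng.normal(size=30) for _ in range(3)]
            pmat = conover_posthoc(groups, ["a", "b", "c"])
            for i, j in (("a", "b"), ("a", "c"), ("b", "c")):
                hits += pmat.loc[i, j] < alpha
                total += 1
        assert 0.02 < hits / total < 0.09


class TestOmnibus:
    def strata_of(self, arrays):
        return [
            PlateletStratum(lab, [ns(f"{lab}{i}", "p", 0, float(v)) for i, v in enumerate(arr)])
            for lab, arr in zip(("low", "normal", "high"), arrays)
        ]

    def test_branch_is_function_of_normality(self):
        rng = np.random.default_rng(1)
        normal = self.strata_of([rng.normal(5, 0.3, 300) for _ in range(3)])
        heavy = self.strata_of([rng.standard_t(1, 300) + 5 for _ in range(3)])
        res_n = omnibus_and_posthoc(normal)
        assert res_n.all_normal and res_n.omnibus_test == "anova"
        res_h = omnibus_and_posthoc(heavy)
        assert not res_h.all_normal and res_h.omnibus_test == "kruskal"
        # the branch is a pure function of the normality outcomes
        for res in (res_n, res_h):
            assert res.omnibus_test == ("anova" if res.all_normal else "kruskal")

    def test_identical_groups_null_case(self):
        vals = np.exp(np.linspace(0, 3, 40))  # decidedly non-normal
        res = omnibus_and_posthoc(self.strata_of([vals, vals, vals]))
        assert res.omnibus_test == "kruskal"
        assert res.statistic == 0.0 and res.pvalue == 1.0
        assert res.posthoc is None

    def test_posthoc_conditional_on_significance(self):
        rng = np.random.default_rng(1)
        sep = self.strata_of(
            [rng.standard_t(2, 200) + mu for mu in (4.0, 5.0, 6.0)]
        )
        res = omnibus_and_posthoc(sep)
        assert res.pvalue < 0.05 and res.posthoc_test == "conover"
        assert res.posthoc.loc["low", "high"] < 0.05

    def test_parametric_branch_runs_tukey(self):
        rng = np.random.default_rng(3)
        sep = self.strata_of([rng.normal(mu, 0.3, 300) for mu in (4.8, 5.0, 5.2)])
        res = omnibus_and_posthoc(sep)
        assert res.omnibus_test == "anova" and res.posthoc_test == "tukey"
        assert res.posthoc.loc["low", "high"] < 0.05

    def test_fewer_than_two_strata_rejected(self):
        with pytest.raises(ValueError):
            omnibus_and_posthoc(self.strata_of([np.ones(5)]))

    def test_holm_adjustment_monotone(self):
        rng = np.random.default_rng(4)
        sep = self.strata_of([rng.standard_t(2, 150) + mu for mu in (4.0, 5.0, 6.0)])
        raw = omnibus_and_posthoc(sep, holm=False)
        adj = omnibus_and_posthoc(sep, holm=True)
        for i in ("low", "normal"):
            for j in ("normal", "high"):
                if i != j:
                    assert adj.posthoc.loc[i, j] >= raw.posthoc.loc[i, j] - 1e-15


class TestMedications:
    MATRIX = {
        "carboplatin": frozenset({"chemotherapy", "platinum"}),
        "pembrolizumab": frozenset({"checkpoint"}),
        "erlotinib": frozenset({"targeted"}),
    }

    def test_platinum_emits_two_events(self):
        events, rejects = map_medications([("p1", "carboplatin", date(2020, 2, 1))], self.MATRIX)
        assert {e.treatment_class for e in events} == {"chemotherapy", "platinum"}
        assert rejects == []

    def test_empty_records(self):
        assert map_medications([], self.MATRIX) == ([], [])

    def test_unknown_medication_rejected_not_fatal(self):
        events, rejects = map_medications([("p1", "unobtainium", date(2020, 2, 1))], self.MATRIX)
        assert events == [] and rejects[0]["reason"] == "unknown medication"

    def test_emitted_classes_contained_in_matrix_row(self):
        rng = np.random.default_rng(6)
        meds = list(self.MATRIX)
        records = [
            (f"p{rng.integers(3)}", meds[rng.integers(len(meds))], date(2020, 1 + int(rng.integers(12)), 1))
            for _ in range(30)
        ]
        events, _ = map_medications(records, self.MATRIX)
        by_key = {(p, m): self.MATRIX[m] for p, m, _ in records}
        for e in events:
            assert any(
                e.treatment_class in classes
                for (p, _m), classes in by_key.items()
                if p == e.patient_id
            )

    def test_bundled_synthetic_matrix_loads(self):
        from importlib import resources

        from oncolex.comparative import read_medication_matrix

        path = resources.files("oncolex.data").joinpath("medication_matrix_synthetic.csv")
        with resources.as_file(path) as p:
            matrix = read_medication_matrix(p)
        assert matrix["carboplatin"] == frozenset({"chemotherapy", "platinum"})
        assert matrix["durvalumab"] == frozenset({"checkpoint"})


class TestTimeline:
    def test_single_event_day_zero(self):
        events = [TreatmentEvent("p1", "chemotherapy", date(2020, 1, 1))]
        table = treatment_timeline([ns("n1", "p1", 0, 5.5)], events)
        assert table == {"chemotherapy": {0: (5.5, 1)}}

    def test_horizon_edge(self):
        events = [TreatmentEvent("p1", "chemotherapy", date(2020, 1, 1))]
        inside = ns("n1", "p1", 42, 5.0)
        outside = ns("n2", "p1", 43, 5.0)
        table = treatment_timeline([inside, outside], events)
        assert set(table["chemotherapy"]) == {42}

    def test_note_counts_once_per_class_day(self):
        # two same-class events with the same start must not double-count
        events = [
            TreatmentEvent("p1", "chemotherapy", date(2020, 1, 1)),
            TreatmentEvent("p1", "platinum", date(2020, 1, 1)),
        ]
        table = treatment_timeline([ns("n1", "p1", 3, 6.0)], events)
        assert table["chemotherapy"][3] == (6.0, 1)
        assert table["platinum"][3] == (6.0, 1)
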