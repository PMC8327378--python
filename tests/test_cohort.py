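"""Cohort building, anchors, demographics, onset labels, occurrences,
and value-series extraction."""

import numpy as np
import pytest

from starcohort import (
    build_cohort,
    demographics,
    has_onset,
    occurs,
    values_for,
)
from starcohort.conditions import Diagnosis, LabValue, Patient, Procedure
from starcohort.errors import ClassMismatchError, DomainError

from .condgen import random_tree, vocabulary
from .oracle import evaluate_reference, reference_cohort


HEART = Procedure(code="35.%", context="ICD-9").age(min_age=18) | \
    Procedure(code="36.1%", context="ICD-9").age(min_age=18)
AKI = Diagnosis(code="584.%", context="ICD-9")


@pytest.fixture()
def surgery_toy(toy):
    """One patient with two surgeries; one with an AKI fact on several
    boundary days; one without anything."""
    valv = toy.concept("procedure", "ICD-9", "35.01", "CLOSED HEART VALVOTOMY")
    aki = toy.concept("diagnosis", "ICD-9", "584.9", "ACUTE KIDNEY FAILURE")
    p1 = toy.patient()
    for day in (10_000, 10_400):
        toy.fact(p1, toy.encounter(p1, day), "procedure", valv, day)
    p2 = toy.patient()
    toy.fact(p2, toy.encounter(p2, 9_000), "procedure", valv, 9_000)
    toy.patient()  # never matches
    return toy, {"valv": valv, "aki": aki, "p1": p1, "p2": p2}


class TestBuildCohort:
    def test_empty_condition_gives_empty_cohort(self, toy):
        c = build_cohort(Diagnosis(code="999.9", context="ICD-9"), toy.db)
        assert len(c) == 0
        assert c.to_frame().empty

    def test_anchor_is_earliest_matching_fact(self, surgery_toy):
        toy, ids = surgery_toy
        c = build_cohort(HEART, toy.db)
        assert c.members == {ids["p1"], ids["p2"]}
        assert c.anchors[ids["p1"]] == 10_000

    def test_members_equal_planted_surgery_patients(self, small_synth):
        db, truth, _ = small_synth
        c = build_cohort(HEART, db)
        planted = truth.anchor_patients()
        assert set(c.members) == set(planted)
        assert c.anchors == planted

    def test_members_match_reference_for_random_trees(self, oracle_db):
        db, _, dump = oracle_db
        vocab = vocabulary(dump)
        rng = np.random.default_rng(3)
        for _ in range(10):
            tree = random_tree(rng, vocab, max_depth=3)
            c = build_cohort(tree, db)
            rows, patients = evaluate_reference(tree, dump)
            members, anchors = reference_cohort(rows, patients, dump)
            assert set(c.members) == members
            assert c.anchors == anchors


class TestDemographics:
    def test_empty_cohort_gives_zero_counts(self, toy):
        c = build_cohort(Diagnosis(code="999", context="ICD-9"), toy.db)
        table = demographics(c)
        assert (table["count"] == 0).all()
        assert table["mean_age_years"].isna().all()

    def test_single_patient_mean_age(self, toy):
        valv = toy.concept("procedure", "ICD-9", "35.01", "CLOSED HEART VALVOTOMY")
        p = toy.patient()
        toy.fact(p, toy.encounter(p, 22_265), "procedure", valv, 22_265)
        table = demographics(build_cohort(Procedure(description="HEART"), toy.db))
        total = table.set_index("gender").loc["total"]
        assert total["count"] == 1
        # 22,265 days / 365.25 days-per-year
        assert total["mean_age_years"] == pytest.approx(60.96, abs=0.05)

    def test_gender_counts_match_planted_truth(self, small_synth):
        db, truth, _ = small_synth
        c = build_cohort(HEART, db)
        table = demographics(c).set_index("gender")
        for gender in ("male", "female"):
            planted = sum(
                1 for pk in truth.anchor_patients()
                if truth.patients[pk]["gender"] == gender
            )
            assert table.loc[gender, "count"] == planted


class TestHasOnset:
    def test_outcome_on_anchor_day_is_not_onset(self, surgery_toy):
        toy, ids = surgery_toy
        toy.fact(ids["p2"], toy.encounter(ids["p2"], 9_000), "diagnosis",
                 ids["aki"], 9_000)
        c = build_cohort(HEART, toy.db)
        label = has_onset(c, "aki", AKI, window_days=None)
        assert label.labels[ids["p2"]] == 0

    def test_window_boundary_is_inclusive(self, surgery_toy):
        toy, ids = surgery_toy
        toy.fact(ids["p2"], toy.encounter(ids["p2"], 9_007), "diagnosis",
                 ids["aki"], 9_007)
        c = build_cohort(HEART, toy.db)
        assert has_onset(c, "aki", AKI, window_days=7).labels[ids["p2"]] == 1
        assert has_onset(c, "aki", AKI, window_days=6).labels[ids["p2"]] == 0

    def test_labels_cover_exactly_the_members(self, surgery_toy):
        toy, ids = surgery_toy
        c = build_cohort(HEART, toy.db)
        label = has_onset(c, "aki", AKI, window_days=7)
        assert set(label.labels) == set(c.members)

    def test_non_positive_window_raises(self, surgery_toy):
        toy, _ = surgery_toy
        c = build_cohort(HEART, toy.db)
        with pytest.raises(DomainError):
            has_onset(c, "aki", AKI, window_days=0)

    @pytest.mark.parametrize("window", [7, 28])
    def test_labels_recover_planted_truth(self, small_synth, window):
        db, truth, _ = small_synth
        c = build_cohort(HEART, db)
        label = has_onset(c, "aki", AKI, window_days=window)
        assert label.labels == truth.onset_labels(window)

    def test_window_monotonicity(self, small_synth):
        db, _, _ = small_synth
        c = build_cohort(HEART, db)
        l7 = has_onset(c, "aki", AKI, window_days=7).labels
        l28 = has_onset(c, "aki", AKI, window_days=28).labels
        lu = has_onset(c, "aki", AKI, window_days=None).labels
        assert all(l7[k] <= l28[k] <= lu[k] for k in l7)


class TestOccurs:
    def test_degenerate_window_counts_anchor_day_only(self, surgery_toy):
        toy, ids = surgery_toy
        toy.fact(ids["p1"], toy.encounter(ids["p1"], 10_000), "diagnosis",
                 ids["aki"], 10_000)
        toy.fact(ids["p1"], toy.encounter(ids["p1"], 10_001), "diagnosis",
                 ids["aki"], 10_001)
        c = build_cohort(HEART, toy.db)
        table = occurs(c, AKI, window=(0, 0)).set_index("patient_key")
        assert table.loc[ids["p1"], "n_occurrences"] == 1

    def test_partial_window_counts(self, surgery_toy):
        toy, ids = surgery_toy
        for day in (9_010, 9_020, 9_400):
            toy.fact(ids["p2"], toy.encounter(ids["p2"], day), "diagnosis",
                     ids["aki"], day)
        c = build_cohort(HEART, toy.db)
        table = occurs(c, AKI, window=(0, 30)).set_index("patient_key")
        assert table.loc[ids["p2"], "n_occurrences"] == 2
        assert table.loc[ids["p2"], "occurred"] == 1

    def test_inverted_window_raises(self, surgery_toy):
        toy, _ = surgery_toy
        c = build_cohort(HEART, toy.db)
        with pytest.raises(DomainError):
            occurs(c, AKI, window=(10, -10))

    def test_counts_match_reference_on_dump(self, oracle_db):
        db, _, dump = oracle_db
        c = build_cohort(HEART, db)
        rng = np.random.default_rng(4)
        vocab = vocabulary(dump)
        for _ in range(8):
            tree = random_tree(rng, vocab, max_depth=2)
            a = int(rng.integers(-300, 0))
            b = int(rng.integers(0, 300))
            table = occurs(c, tree, window=(a, b)).set_index("patient_key")
            rows, _ = evaluate_reference(tree, dump)
            for pk in c.members:
                expected = sum(
                    1 for r in rows
                    if dump.fact_patient.get(r[1], dump.enc_patient.get(r[2])) == pk
                    and a <= _row_day(r, dump) - c.anchors[pk] <= b
                )
                assert table.loc[pk, "n_occurrences"] == expected

    def test_nested_windows_are_monotone(self, small_synth):
        db, _, _ = small_synth
        c = build_cohort(HEART, db)
        inner = occurs(c, AKI, window=(0, 7))["n_occurrences"]
        outer = occurs(c, AKI, window=(-7, 14))["n_occurrences"]
        assert (inner <= outer).all()


def _row_day(row, dump):
    dimension, fact_key, encounter_key, _ = row
    if dimension == "encounter":
        for e in dump.encounters:
            if int(e["encounter_key"]) == encounter_key:
                return int(e["begin_day"])
    for f in dump.facts:
        if f["fact_key"] == fact_key:
            return int(f["time_day"])
    raise KeyError(row)


class TestValuesFor:
    def test_value_less_class_raises(self, small_synth):
        db, _, _ = small_synth
        c = build_cohort(HEART, db)
        with pytest.raises(ClassMismatchError):
            values_for(c, AKI)

    def test_preanchor_glucose_draws_match_planted_truth(self, small_synth):
        db, truth, _ = small_synth
        c = build_cohort(HEART, db)
        series = values_for(c, LabValue("GLUCOSE"), window=(-180, 0))
        got = {
            (int(r.patient_key), int(r.time_day), round(float(r.numeric_value), 4))
            for r in series.itertuples(index=False)
        }
        expected = set()
        for pk, anchor in truth.anchor_patients().items():
            for day, value in truth.patients[pk]["numeric_draws"].get("GLU", []):
                if -180 <= day - anchor <= 0:
                    expected.add((pk, day, round(value, 4)))
        assert got == expected

    def test_rel_day_is_consistent_with_anchors(self, small_synth):
        db, _, _ = small_synth
        c = build_cohort(HEART, db)
        series = values_for(c, LabValue("CREATININE"), window=(-30, 30))
        for r in series.itertuples(index=False):
            assert r.rel_day == r.time_day - c.anchors[int(r.patient_key)]
            assert -30 <= r.rel_day <= 30


def test_patient_only_cohort_has_birth_anchor(toy):
    toy.patient(gender="male")
    toy.patient(gender="female")
    c = build_cohort(Patient(gender="male"), toy.db)
    assert c.members == {1}
    assert c.anchors[1] == 0
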