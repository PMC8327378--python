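"""Condition construction, algebra semantics, age filters, and JSON."""

import numpy as np
import pytest

from starcohort import conditions
from starcohort.conditions import (
    Diagnosis,
    Encounter,
    LabValue,
    Patient,
    Procedure,
    combine,
    evaluate,
    evaluate_with_patients,
    from_json,
    make_condition,
    to_json,
    with_age,
)
from starcohort.errors import (
    AmbiguityError,
    ArityError,
    ConditionParseError,
    DomainError,
    SchemaVersionError,
    UnsupportedInitializationError,
)

from .condgen import random_tree, vocabulary
from .oracle import code_matches, evaluate_reference, frame_row_ids


class TestMakeCondition:
    @pytest.mark.parametrize(
        "kwargs, error",
        [
            (dict(code="X", context="LOCAL"), UnsupportedInitializationError),
            (dict(code="X"), UnsupportedInitializationError),  # missing context
        ],
    )
    def test_description_only_classes_reject_codes(self, kwargs, error):
        for cls in ("Encounter", "Metadata", "Patient"):
            with pytest.raises(error):
                make_condition(cls, **kwargs)

    def test_code_and_description_together_is_ambiguous(self):
        with pytest.raises(AmbiguityError):
            make_condition("Diagnosis", code="584.9", context="ICD-9",
                           description="ACUTE KIDNEY FAILURE")

    def test_code_without_context_is_rejected(self):
        with pytest.raises(UnsupportedInitializationError):
            make_condition("Procedure", code="35.0")

    def test_no_initialization_is_rejected(self):
        with pytest.raises(UnsupportedInitializationError):
            make_condition("Diagnosis")

    def test_constructor_sugar_matches_make_condition(self):
        assert Procedure("35.0", "ICD-9") == make_condition(
            "Procedure", code="35.0", context="ICD-9"
        )
        assert LabValue("GLUCOSE") == make_condition("LabValue", description="GLUCOSE")
        assert Patient(gender="male") == make_condition(
            "Patient", attributes={"gender": "male"}
        )


class TestWildcardSemantics:
    CODES = ["584.5", "584.9", "58.4", "5845", "584.", "V58.4", "250.00"]

    @pytest.mark.parametrize(
        "pattern, expected",
        [
            ("584.%", {"584.5", "584.9", "584."}),
            ("584.9", {"584.9"}),
            ("58.4", {"58.4"}),
            ("%58.4", {"58.4", "V58.4"}),
            ("5%", {"584.5", "584.9", "58.4", "5845", "584."}),
        ],
    )
    def test_pattern_matching_on_enumerated_code_list(self, pattern, expected, toy):
        # the reference matcher by enumeration
        assert {c for c in self.CODES if code_matches(pattern, c)} == expected
        # and the SQL path on a toy dimension holding the same codes
        p = toy.patient()
        e = toy.encounter(p, 10)
        for code in self.CODES:
            c = toy.concept("diagnosis", "ICD-9", code, f"DX {code}")
            toy.fact(p, e, "diagnosis", c, 10)
        frame = evaluate(Diagnosis(code=pattern, context="ICD-9"), toy.db)
        assert set(frame["code"]) == expected


class TestCodeDescriptionEquivalence:
    def test_same_patient_set_from_code_and_description(self, toy):
        """A code and the description it maps to are two routes to the
        same concept, hence to identical patient sets."""
        valv = toy.concept("procedure", "ICD-9", "35.0", "CLOSED HEART VALVOTOMY")
        other = toy.concept("procedure", "ICD-9", "36.10", "AORTOCORONARY BYPASS")
        for day in (9000, 12000, 15000):
            p = toy.patient()
            e = toy.encounter(p, day)
            toy.fact(p, e, "procedure", valv if day < 15000 else other, day)
        by_code = evaluate(Procedure(code="35.0", context="ICD-9"), toy.db)
        by_desc = evaluate(Procedure(description="CLOSED HEART VALVOTOMY"), toy.db)
        assert set(by_code["patient_key"]) == set(by_desc["patient_key"]) == {1, 2}


class TestAgeFilter:
    def _db_with_fact_at(self, toy, day):
        p = toy.patient()
        e = toy.encounter(p, day)
        c = toy.concept("procedure", "ICD-9", "35.0", "CLOSED HEART VALVOTOMY")
        toy.fact(p, e, "procedure", c, day)
        return toy.db

    def test_fact_on_the_18th_birthday_is_retained(self, toy):
        db = self._db_with_fact_at(toy, 6574)  # 18 years in whole days
        cond = Procedure(code="35.0", context="ICD-9").age(min_age=18)
        assert len(evaluate(cond, db)) == 1

    def test_fact_one_day_younger_is_excluded(self, toy):
        db = self._db_with_fact_at(toy, 6573)
        cond = Procedure(code="35.0", context="ICD-9").age(min_age=18)
        assert len(evaluate(cond, db)) == 0

    def test_zero_min_age_is_identity(self, toy):
        db = self._db_with_fact_at(toy, 100)
        base = Procedure(code="35.0", context="ICD-9")
        assert len(evaluate(base.age(min_age=0), db)) == len(evaluate(base, db))

    def test_negative_age_raises(self):
        with pytest.raises(DomainError):
            Procedure(code="35.0", context="ICD-9").age(min_age=-1)

    def test_inverted_bounds_raise(self):
        with pytest.raises(DomainError):
            with_age(Procedure(code="35.0", context="ICD-9"), 70, 18)


class TestCombine:
    def test_fewer_than_two_operands_raises(self):
        with pytest.raises(ArityError):
            combine("or", Diagnosis(code="584.9", context="ICD-9"))

    def test_multiple_facts_per_patient_are_all_returned(self, toy):
        p = toy.patient()
        c = toy.concept("procedure", "ICD-9", "35.0", "CLOSED HEART VALVOTOMY")
        for day in (10_000, 10_400):
            e = toy.encounter(p, day)
            toy.fact(p, e, "procedure", c, day)
        frame = evaluate(Procedure(description="HEART"), toy.db)
        assert len(frame) == 2
        assert set(frame["time_day"]) == {10_000, 10_400}

    def test_evaluate_on_empty_database(self, toy):
        frame = evaluate(Diagnosis(code="584.%", context="ICD-9"), toy.db)
        assert len(frame) == 0

    def test_mixed_class_and_is_patient_level(self, toy):
        """male AND (procedure A OR procedure B) keeps the procedure facts
        of male patients only."""
        a = toy.concept("procedure", "ICD-9", "35.0", "CLOSED HEART VALVOTOMY")
        b = toy.concept("procedure", "ICD-9", "36.1", "AORTOCORONARY BYPASS")
        male = toy.patient(gender="male")
        female = toy.patient(gender="female")
        for pk, ck in ((male, a), (female, b)):
            e = toy.encounter(pk, 9000)
            toy.fact(pk, e, "procedure", ck, 9000)
        cond = (Procedure(code="35.0", context="ICD-9")
                | Procedure(code="36.1", context="ICD-9")) & Patient(gender="male")
        frame, patients = evaluate_with_patients(cond, toy.db)
        assert patients == {male}
        assert set(frame["patient_key"]) == {male}


class TestAlgebraAgainstOracle:
    """Randomized equivalence and algebraic laws versus the in-memory
    reference evaluator."""

    N_TREES = 40

    def test_random_trees_match_reference(self, oracle_db):
        db, _, dump = oracle_db
        vocab = vocabulary(dump)
        rng = np.random.default_rng(0)
        for _ in range(self.N_TREES):
            tree = random_tree(rng, vocab)
            frame, patients = evaluate_with_patients(tree, db)
            ref_rows, ref_patients = evaluate_reference(tree, dump)
            assert frame_row_ids(frame) == ref_rows
            assert patients == ref_patients

    def test_set_algebra_laws(self, oracle_db):
        db, _, dump = oracle_db
        vocab = vocabulary(dump)
        rng = np.random.default_rng(1)
        for _ in range(15):
            a = random_tree(rng, vocab, max_depth=2)
            b = random_tree(rng, vocab, max_depth=2)
            c = random_tree(rng, vocab, max_depth=2)
            pa = evaluate_with_patients(a, db)[1]
            pb = evaluate_with_patients(b, db)[1]
            pc = evaluate_with_patients(c, db)[1]
            p_or = evaluate_with_patients(a | b, db)[1]
            p_and = evaluate_with_patients(a & b, db)[1]
            # commutativity
            assert p_or == evaluate_with_patients(b | a, db)[1] == pa | pb
            assert p_and == evaluate_with_patients(b & a, db)[1] == pa & pb
            # associativity
            assert (evaluate_with_patients((a | b) | c, db)[1]
                    == evaluate_with_patients(a | (b | c), db)[1] == pa | pb | pc)
            assert (evaluate_with_patients((a & b) & c, db)[1]
                    == evaluate_with_patients(a & (b & c), db)[1] == pa & pb & pc)
            # idempotence, monotonicity, antitonicity
            assert evaluate_with_patients(a | a, db)[1] == pa
            assert pa <= p_or
            assert p_and <= pa


class TestJsonRoundTrip:
    def test_round_trip_is_structural_identity(self, oracle_db):
        _, _, dump = oracle_db
        vocab = vocabulary(dump)
        rng = np.random.default_rng(2)
        for _ in range(60):
            tree = random_tree(rng, vocab)
            assert from_json(to_json(tree)) == tree

    def test_heart_surgery_condition_round_trips_to_same_patient_set(self, oracle_db):
        db, _, _ = oracle_db
        cond = (Procedure(code="35.%", context="ICD-9").age(min_age=18)
                | Procedure(code="36.1%", context="ICD-9").age(min_age=18))
        reloaded = from_json(to_json(cond))
        assert reloaded == cond
        assert (evaluate_with_patients(cond, db)[1]
                == evaluate_with_patients(reloaded, db)[1])

    def test_unknown_condition_class_raises_schema_version_error(self):
        doc = to_json(Diagnosis(code="584.%", context="ICD-9")).replace(
            "Diagnosis", "Frobnicate"
        )
        with pytest.raises(SchemaVersionError):
            from_json(doc)

    def test_unknown_version_raises(self):
        doc = to_json(Diagnosis(code="584.%", context="ICD-9")).replace(
            '"version": "1"', '"version": "99"'
        )
        with pytest.raises(SchemaVersionError):
            from_json(doc)

    @pytest.mark.parametrize("doc", ["{not json", '{"root": 5}', '["list"]'])
    def test_malformed_documents_raise_parse_error(self, doc):
        with pytest.raises((ConditionParseError, SchemaVersionError)):
            from_json(doc)


def test_encounter_condition_matches_by_type_substring(toy):
    p1, p2 = toy.patient(), toy.patient()
    toy.encounter(p1, 100, kind="inpatient")
    toy.encounter(p2, 200, kind="outpatient")
    frame, patients = evaluate_with_patients(Encounter("INPATIENT"), toy.db)
    assert patients == {p1}
    assert list(frame["time_day"]) == [100]
    # "PATIENT" is a substring of both types
    assert evaluate_with_patients(Encounter("PATIENT"), toy.db)[1] == {p1, p2}
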