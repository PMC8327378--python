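"""Tiny hand-built warehouse builder for fixture construction."""

from __future__ import annotations

from starcohort import schema
from starcohort.schema import DatabaseHandle, create_schema, insert_rows


class Toy:
    """Incremental builder: create patients, encounters, concepts, groups
    and facts row by row; rows are written immediately so planted defects
    (bad references, inverted days) go straight into the tables."""

    def __init__(self, path: str):
        self.db: DatabaseHandle = create_schema(str(path))
        self._pk = self._ek = self._ck = self._gk = self._fk = 0
        self._singleton: dict[int, int] = {}
        self._table = {
            "procedure": "fd_procedure",
            "diagnosis": "fd_diagnosis",
            "material": "fd_material",
            "metadata": "d_metadata",
        }

    def patient(self, gender="male", race=None, deceased=0, birth_offset=0) -> int:
        self._pk += 1
        insert_rows(
            self.db, "d_person",
            ("patient_key", "mrn", "gender", "birth_offset_days", "race", "deceased"),
            [(self._pk, f"T{self._pk:05d}", gender, birth_offset, race, deceased)],
        )
        return self._pk

    def encounter(self, patient, day, end=None, kind="outpatient") -> int:
        self._ek += 1
        insert_rows(
            self.db, "d_encounter",
            ("encounter_key", "patient_key", "encounter_type", "begin_day", "end_day"),
            [(self._ek, patient, kind, day, day if end is None else end)],
        )
        return self._ek

    def concept(self, dimension, context, code, description) -> int:
        self._ck += 1
        insert_rows(
            self.db, self._table[dimension],
            ("concept_key", "context_name", "code", "description"),
            [(self._ck, context, code, description.upper())],
        )
        return self._ck

    def group(self, *concept_keys) -> int:
        self._gk += 1
        insert_rows(
            self.db, "group_map", ("group_key", "concept_key"),
            [(self._gk, ck) for ck in concept_keys],
        )
        return self._gk

    def fact(self, patient, encounter, dimension, concept, day,
             value=None, unit=None, grouped=False) -> int:
        """Add one fact; ``concept`` is a concept key (wrapped in a
        singleton group automatically) or, with ``grouped=True``, an
        existing group key."""
        self._fk += 1
        links = {"procedure": None, "diagnosis": None, "material": None}
        metadata_key = None
        if dimension == "metadata":
            metadata_key = concept
        elif grouped:
            links[dimension] = concept
        else:
            if concept not in self._singleton:
                self._singleton[concept] = self.group(concept)
            links[dimension] = self._singleton[concept]
        insert_rows(
            self.db, "fact",
            ("fact_key", "patient_key", "encounter_key", "procedure_group_key",
             "diagnosis_group_key", "material_group_key", "metadata_key",
             "time_day", "numeric_value", "text_value", "unit"),
            [(self._fk, patient, encounter, links["procedure"], links["diagnosis"],
              links["material"], metadata_key, day, value, None, unit)],
        )
        return self._fk

    def raw_fact(self, **columns) -> int:
        """Insert a fact with explicit column values (defect planting)."""
        self._fk += 1
        row = {
            "fact_key": self._fk, "patient_key": 1, "encounter_key": 1,
            "procedure_group_key": None, "diagnosis_group_key": None,
            "material_group_key": None, "metadata_key": None,
            "time_day": 0, "numeric_value": None, "text_value": None, "unit": None,
        }
        row.update(columns)
        insert_rows(self.db, "fact", tuple(row), [tuple(row.values())])
        return self._fk
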