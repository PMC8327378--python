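"""Simplified i2b2-style star schema: DDL, validation, and fact retrieval.

The physical model is deliberately narrow — the smallest schema that still
exercises the fact → group → dimension join structure of a star-schema
clinical data warehouse:

======================  =====================================================
table                   contents
======================  =====================================================
``fact``                one row per atomic observation; links a patient, an
                        encounter, at most one group/concept per dimension,
                        a day-granular timestamp and an optional value
``d_person``            patients (deidentified MRN, gender, race, deceased)
``d_encounter``         inpatient/outpatient/emergency encounters with
                        begin/end days
``fd_procedure``        procedure concepts (context, code, description)
``fd_diagnosis``        diagnosis concepts
``fd_material``         material/drug concepts
``d_metadata``          metadata concepts; laboratory tests live here
``group_map``           group_key → concept_key mapping; facts always point
                        at group keys, singleton groups wrap lone concepts
======================  =====================================================

Timestamps are integers, "age of the patient in days" — the convention of a
deidentified warehouse where every patient carries a private day-offset
timeline and ``birth_offset_days`` is pinned at 0.  Concept descriptions are
stored uppercase; matching uppercases its input.
"""

from __future__ import annotations

import os
import sqlite3
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import PlanError, SchemaConflictError

SCHEMA_VERSION = 1

#: dimensions whose concepts are reached through ``group_map``
GROUPED_DIMENSIONS = ("procedure", "diagnosis", "material")
#: all concept dimensions (metadata links directly, without grouping)
DIMENSIONS = GROUPED_DIMENSIONS + ("metadata",)

GENDERS = ("male", "female", "unknown")
ENCOUNTER_TYPES = ("inpatient", "outpatient", "emergency")

#: contexts whose facts must carry a numeric value (labs and vital signs)
VALUE_BEARING_CONTEXTS = ("LAB", "VITALS")

TABLES = (
    "fact",
    "d_person",
    "d_encounter",
    "fd_procedure",
    "fd_diagnosis",
    "fd_material",
    "d_metadata",
    "group_map",
)

_CONCEPT_TABLE = {
    "procedure": "fd_procedure",
    "diagnosis": "fd_diagnosis",
    "material": "fd_material",
    "metadata": "d_metadata",
}

_DDL = """
CREATE TABLE d_person (
    patient_key       INTEGER PRIMARY KEY,
    mrn               TEXT NOT NULL UNIQUE,
    gender            TEXT NOT NULL,
    birth_offset_days INTEGER NOT NULL DEFAULT 0,
    race              TEXT,
    deceased          INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE d_encounter (
    encounter_key  INTEGER PRIMARY KEY,
    patient_key    INTEGER NOT NULL,
    encounter_type TEXT NOT NULL,
    begin_day      INTEGER NOT NULL,
    end_day        INTEGER NOT NULL
);
CREATE TABLE fd_procedure (
    concept_key  INTEGER PRIMARY KEY,
    context_name TEXT NOT NULL,
    code         TEXT NOT NULL,
    description  TEXT NOT NULL,
    UNIQUE (context_name, code)
);
CREATE TABLE fd_diagnosis (
    concept_key  INTEGER PRIMARY KEY,
    context_name TEXT NOT NULL,
    code         TEXT NOT NULL,
    description  TEXT NOT NULL,
    UNIQUE (context_name, code)
);
CREATE TABLE fd_material (
    concept_key  INTEGER PRIMARY KEY,
    context_name TEXT NOT NULL,
    code         TEXT NOT NULL,
    description  TEXT NOT NULL,
    UNIQUE (context_name, code)
);
CREATE TABLE d_metadata (
    concept_key  INTEGER PRIMARY KEY,
    context_name TEXT NOT NULL,
    code         TEXT NOT NULL,
    description  TEXT NOT NULL,
    UNIQUE (context_name, code)
);
CREATE TABLE group_map (
    group_key   INTEGER NOT NULL,
    concept_key INTEGER NOT NULL,
    PRIMARY KEY (group_key, concept_key)
);
CREATE TABLE fact (
    fact_key            INTEGER PRIMARY KEY,
    patient_key         INTEGER NOT NULL,
    encounter_key       INTEGER NOT NULL,
    procedure_group_key INTEGER,
    diagnosis_group_key INTEGER,
    material_group_key  INTEGER,
    metadata_key        INTEGER,
    time_day            INTEGER NOT NULL,
    numeric_value       REAL,
    text_value          TEXT,
    unit                TEXT
);
CREATE INDEX ix_fact_patient ON fact (patient_key);
CREATE INDEX ix_fact_time ON fact (time_day);
CREATE INDEX ix_fact_procedure ON fact (procedure_group_key);
CREATE INDEX ix_fact_diagnosis ON fact (diagnosis_group_key);
CREATE INDEX ix_fact_material ON fact (material_group_key);
CREATE INDEX ix_fact_metadata ON fact (metadata_key);
CREATE INDEX ix_group_concept ON group_map (concept_key);
CREATE INDEX ix_encounter_patient ON d_encounter (patient_key);
"""

#: columns of every fact frame returned by :func:`fetch_facts`
FACT_COLUMNS = [
    "fact_key",
    "patient_key",
    "mrn",
    "encounter_key",
    "time_day",
    "dimension",
    "concept_key",
    "context_name",
    "code",
    "description",
    "numeric_value",
    "text_value",
    "unit",
]


_FACT_DTYPES = {
    "fact_key": "float64",  # NaN for encounter pseudo-facts
    "patient_key": "int64",
    "mrn": "object",
    "encounter_key": "int64",
    "time_day": "int64",
    "dimension": "object",
    "concept_key": "float64",
    "context_name": "object",
    "code": "object",
    "description": "object",
    "numeric_value": "float64",
    "text_value": "object",
    "unit": "object",
}


def _canonical(frame: pd.DataFrame) -> pd.DataFrame:
    return frame[FACT_COLUMNS].astype(_FACT_DTYPES)


@dataclass(frozen=True)
class DatabaseHandle:
    """Connection descriptor for a star-schema SQLite database."""

    path: str
    schema_version: int = SCHEMA_VERSION

    def connect(self) -> sqlite3.Connection:
        return sqlite3.connect(self.path)


@dataclass(frozen=True)
class FactSelector:
    """Leaf-level query plan: one dimension, one pattern, value/age limits.

    ``code_pattern`` uses ``%`` as a multi-character wildcard and is
    case-sensitive; ``description_pattern`` is a case-insensitive literal
    substring.  ``min_day``/``max_day`` are precomputed day bounds for the
    age filter (already including the half-day rounding of the day-granular
    age convention).  ``dimension`` may also be the pseudo-dimensions
    ``"encounter"`` and ``"patient"``.
    """

    dimension: str
    context_name: str | None = None
    code_pattern: str | None = None
    description_pattern: str | None = None
    require_numeric: bool = False
    attributes: Mapping[str, object] | None = None
    min_day: float | None = None
    max_day: float | None = None


@dataclass(frozen=True)
class Violation:
    """One referential-integrity or invariant violation found by :func:`validate`."""

    table: str
    row_key: object
    rule: str


def create_schema(target: str) -> DatabaseHandle:
    """Create an empty star schema at ``target`` (SQLite file path).

    Raises :class:`SchemaConflictError` if any of the schema tables already
    exist at the target, and ``OSError`` when the path is not writable.
    """
    existing = _existing_tables(target) if os.path.exists(target) else set()
    conflict = existing & set(TABLES)
    if conflict:
        raise SchemaConflictError(
            f"target {target!r} already contains tables {sorted(conflict)}"
        )
    # fail eagerly on unwritable paths instead of inside executescript
    directory = os.path.dirname(os.path.abspath(target))
    if not os.access(directory, os.W_OK):
        raise OSError(f"directory {directory!r} is not writable")
    with sqlite3.connect(target) as conn:
        conn.executescript(_DDL)
        conn.execute(f"PRAGMA user_version = {SCHEMA_VERSION}")
    return DatabaseHandle(path=target, schema_version=SCHEMA_VERSION)


def open_database(path: str) -> DatabaseHandle:
    """Open an existing star-schema database, checking the table set."""
    if not os.path.exists(path):
        raise OSError(f"database file {path!r} does not exist")
    missing = set(TABLES) - _existing_tables(path)
    if missing:
        raise SchemaConflictError(f"{path!r} lacks schema tables {sorted(missing)}")
    with sqlite3.connect(path) as conn:
        version = conn.execute("PRAGMA user_version").fetchone()[0]
    return DatabaseHandle(path=path, schema_version=version)


def _existing_tables(path: str) -> set[str]:
    try:
        with sqlite3.connect(path) as conn:
            rows = conn.execute(
                "SELECT name FROM sqlite_master WHERE type = 'table'"
            ).fetchall()
    except sqlite3.DatabaseError as exc:  # not a SQLite file at all
        raise SchemaConflictError(f"{path!r} is not a SQLite database: {exc}") from exc
    return {r[0] for r in rows}


def insert_rows(
    db: DatabaseHandle, table: str, columns: Sequence[str], rows: Iterable[Sequence]
) -> None:
    """Bulk-insert rows; the loader used by the synthetic generator and tests."""
    placeholders = ", ".join("?" for _ in columns)
    sql = f"INSERT INTO {table} ({', '.join(columns)}) VALUES ({placeholders})"
    with db.connect() as conn:
        conn.executemany(sql, rows)


def dump_tables(db: DatabaseHandle) -> dict[str, pd.DataFrame]:
    """Full dump of all eight tables as data frames (oracle/testing aid)."""
    with db.connect() as conn:
        return {t: pd.read_sql_query(f"SELECT * FROM {t}", conn) for t in TABLES}


# ---------------------------------------------------------------------------
# validation


def validate(db: DatabaseHandle) -> list[Violation]:
    """Re-check every schema invariant over all rows.

    Violations are data, not exceptions: an empty list means the database
    is internally consistent.  Checks cover key positivity/uniqueness,
    encounter day ordering, referential integrity of every fact link,
    group-dimension homogeneity, and the rule that facts resolving to
    value-bearing contexts (labs, vitals) carry a numeric value.
    """
    v: list[Violation] = []
    t = dump_tables(db)
    person, enc, fact, gmap = t["d_person"], t["d_encounter"], t["fact"], t["group_map"]

    for _, row in person.iterrows():
        if row["patient_key"] <= 0:
            v.append(Violation("d_person", row["patient_key"], "patient_key must be positive"))
        if row["gender"] not in GENDERS:
            v.append(Violation("d_person", row["patient_key"], "gender outside enum"))
        if row["birth_offset_days"] != 0:
            v.append(Violation("d_person", row["patient_key"], "birth_offset_days must be 0"))
    if person["mrn"].duplicated().any():
        for key in person.loc[person["mrn"].duplicated(), "patient_key"]:
            v.append(Violation("d_person", key, "duplicate mrn"))

    patient_keys = set(person["patient_key"])
    for _, row in enc.iterrows():
        if row["begin_day"] > row["end_day"]:
            v.append(Violation("d_encounter", row["encounter_key"], "begin_day > end_day"))
        if row["patient_key"] not in patient_keys:
            v.append(Violation("d_encounter", row["encounter_key"], "unknown patient_key"))

    # concept tables: non-empty descriptions, globally unique concept keys
    concept_dim: dict[int, str] = {}
    value_bearing: set[int] = set()
    for dim in DIMENSIONS:
        table = _CONCEPT_TABLE[dim]
        for _, row in t[table].iterrows():
            key = row["concept_key"]
            if not row["description"]:
                v.append(Violation(table, key, "empty description"))
            if key in concept_dim:
                v.append(Violation(table, key, "concept_key reused across dimensions"))
            concept_dim[key] = dim
            if row["context_name"] in VALUE_BEARING_CONTEXTS:
                value_bearing.add(key)

    group_dims: dict[int, set[str]] = {}
    group_members: dict[int, set[int]] = {}
    for _, row in gmap.iterrows():
        gk, ck = row["group_key"], row["concept_key"]
        if ck not in concept_dim:
            v.append(Violation("group_map", gk, "concept_key does not resolve"))
            continue
        group_dims.setdefault(gk, set()).add(concept_dim[ck])
        group_members.setdefault(gk, set()).add(ck)
    for gk, dims in group_dims.items():
        if len(dims) > 1:
            v.append(Violation("group_map", gk, "group spans multiple dimensions"))

    encounter_keys = set(enc["encounter_key"])
    metadata_keys = {k for k, d in concept_dim.items() if d == "metadata"}
    link_cols = ["procedure_group_key", "diagnosis_group_key", "material_group_key", "metadata_key"]
    for row in fact.itertuples(index=False):
        fk = row.fact_key
        links = [getattr(row, c) for c in link_cols]
        if all(pd.isna(x) for x in links):
            v.append(Violation("fact", fk, "no concept link set"))
        if row.patient_key not in patient_keys:
            v.append(Violation("fact", fk, "unknown patient_key"))
        if row.encounter_key not in encounter_keys:
            v.append(Violation("fact", fk, "unknown encounter_key"))
        if row.time_day < 0:
            v.append(Violation("fact", fk, "negative time_day"))
        resolved: set[int] = set()
        for col, expected_dim in zip(link_cols[:3], GROUPED_DIMENSIONS):
            gk = getattr(row, col)
            if pd.isna(gk):
                continue
            members = group_members.get(int(gk))
            if not members:
                v.append(Violation("fact", fk, f"{col} does not resolve"))
            elif group_dims[int(gk)] != {expected_dim}:
                v.append(Violation("fact", fk, f"{col} points at wrong dimension"))
            else:
                resolved |= members
        if not pd.isna(row.metadata_key):
            if int(row.metadata_key) not in metadata_keys:
                v.append(Violation("fact", fk, "metadata_key does not resolve"))
            else:
                resolved.add(int(row.metadata_key))
        if resolved & value_bearing and pd.isna(row.numeric_value):
            v.append(Violation("fact", fk, "value-bearing fact lacks numeric_value"))
    return v


# ---------------------------------------------------------------------------
# fact retrieval


def _escape_like(text: str) -> str:
    return text.replace("\\", "\\\\").replace("%", "\\%").replace("_", "\\_")


def _code_predicate(column: str, pattern: str, params: list) -> str:
    if "%" in pattern:
        like = "".join(
            "%" if ch == "%" else _escape_like(ch) for ch in pattern
        )
        params.append(like)
        return f"{column} LIKE ? ESCAPE '\\'"
    params.append(pattern)
    return f"{column} = ?"


def _description_predicate(column: str, pattern: str, params: list) -> str:
    params.append(f"%{_escape_like(pattern.upper())}%")
    return f"UPPER({column}) LIKE ? ESCAPE '\\'"


def fetch_facts(db: DatabaseHandle, plan: FactSelector) -> pd.DataFrame:
    """Execute one leaf selector and return matching fact rows.

    The result joins FACT → group_map → dimension table (or FACT →
    d_metadata directly), one row per (fact, resolved concept) pair, in no
    guaranteed order.  Encounter selectors return pseudo-fact rows, one per
    matching encounter, timestamped at ``begin_day``.
    """
    if plan.dimension == "patient":
        raise PlanError("patient selectors match patients, not facts; use fetch_patients")
    if plan.dimension == "encounter":
        return _fetch_encounter_rows(db, plan)
    if plan.dimension not in DIMENSIONS:
        raise PlanError(f"unknown dimension {plan.dimension!r}")

    params: list = []
    where: list[str] = []
    if plan.context_name is not None:
        where.append("d.context_name = ?")
        params.append(plan.context_name)
    if plan.code_pattern is not None:
        where.append(_code_predicate("d.code", plan.code_pattern, params))
    if plan.description_pattern is not None:
        where.append(_description_predicate("d.description", plan.description_pattern, params))
    if plan.require_numeric:
        where.append("f.numeric_value IS NOT NULL")
    if plan.min_day is not None:
        where.append("f.time_day >= ?")
        params.append(plan.min_day)
    if plan.max_day is not None:
        where.append("f.time_day <= ?")
        params.append(plan.max_day)

    table = _CONCEPT_TABLE[plan.dimension]
    if plan.dimension in GROUPED_DIMENSIONS:
        join = (
            f"JOIN group_map g ON g.group_key = f.{plan.dimension}_group_key "
            f"JOIN {table} d ON d.concept_key = g.concept_key"
        )
    else:
        join = f"JOIN {table} d ON d.concept_key = f.metadata_key"
    sql = (
        "SELECT f.fact_key, f.patient_key, p.mrn, f.encounter_key, f.time_day, "
        f"'{plan.dimension}' AS dimension, d.concept_key, d.context_name, d.code, "
        "d.description, f.numeric_value, f.text_value, f.unit "
        "FROM fact f JOIN d_person p ON p.patient_key = f.patient_key "
        + join
    )
    if where:
        sql += " WHERE " + " AND ".join(where)
    with db.connect() as conn:
        frame = pd.read_sql_query(sql, conn, params=params)
    return _canonical(frame)


def _fetch_encounter_rows(db: DatabaseHandle, plan: FactSelector) -> pd.DataFrame:
    params: list = []
    where: list[str] = []
    if plan.description_pattern is not None:
        where.append(_description_predicate("e.encounter_type", plan.description_pattern, params))
    if plan.min_day is not None:
        where.append("e.begin_day >= ?")
        params.append(plan.min_day)
    if plan.max_day is not None:
        where.append("e.begin_day <= ?")
        params.append(plan.max_day)
    sql = (
        "SELECT NULL AS fact_key, e.patient_key, p.mrn, e.encounter_key, "
        "e.begin_day AS time_day, 'encounter' AS dimension, NULL AS concept_key, "
        "'ENCOUNTER' AS context_name, NULL AS code, UPPER(e.encounter_type) AS description, "
        "NULL AS numeric_value, NULL AS text_value, NULL AS unit "
        "FROM d_encounter e JOIN d_person p ON p.patient_key = e.patient_key"
    )
    if where:
        sql += " WHERE " + " AND ".join(where)
    with db.connect() as conn:
        frame = pd.read_sql_query(sql, conn, params=params)
    return _canonical(frame)


_PATIENT_ATTRIBUTES = ("gender", "race", "deceased", "mrn")


def fetch_patients(db: DatabaseHandle, plan: FactSelector) -> set[int]:
    """Patient keys matched by a patient-attribute selector.

    With ``attributes`` the match is exact per attribute; with a
    description pattern the case-insensitive substring is matched against
    gender and race.
    """
    params: list = []
    where: list[str] = []
    if plan.attributes:
        for name, value in plan.attributes.items():
            if name not in _PATIENT_ATTRIBUTES:
                raise PlanError(f"unknown patient attribute {name!r}")
            where.append(f"{name} = ?")
            params.append(int(value) if name == "deceased" else value)
    elif plan.description_pattern is not None:
        g = _description_predicate("gender", plan.description_pattern, [])
        r = _description_predicate("COALESCE(race, '')", plan.description_pattern, [])
        esc = f"%{_escape_like(plan.description_pattern.upper())}%"
        where.append(f"({g} OR {r})")
        params.extend([esc, esc])
    sql = "SELECT patient_key FROM d_person"
    if where:
        sql += " WHERE " + " AND ".join(where)
    with db.connect() as conn:
        return {row[0] for row in conn.execute(sql, params).fetchall()}
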