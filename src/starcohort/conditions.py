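"""Condition algebra for phenotype definitions.

A condition is a tree: leaves select facts out of one dimension of the
star schema (by clinical code, by description substring, or by patient
attribute), and inner nodes combine children with Boolean AND/OR.  A
condition can be evaluated against a database (returning every matching
fact row), serialized to JSON for sharing, and handed to the cohort layer.

Condition classes mirror the classic phenotyping vocabulary::

    Diagnosis, Procedure, Measurement (procedure), VitalSign (measurement),
    Material, Drug (material), Encounter, Metadata, LabValue, Patient

Classes in parentheses are parents: a subclass selects a subset of the
parent's facts (e.g. ``Measurement`` is a ``Procedure`` whose facts carry a
numeric value).  ``Encounter``, ``Metadata`` and ``Patient`` can only be
initialized from descriptions/attributes; the rest also accept a
``(code, context)`` pair where ``%`` acts as a multi-character wildcard
(``"584.%"`` selects the whole ICD-9 584 family).

Semantics, fixed and documented:

* OR is the row-union of the children's fact sets; AND intersects at
  *patient* granularity (the patient must satisfy every operand; fact-level
  or same-encounter conjunction is deliberately out of scope).  For AND
  over a single condition class the surviving rows are the left operand's,
  otherwise the union of all operands' rows restricted to the intersection.
* There is no NOT.
* ``.age(min_age=…, max_age=…)`` restricts matching facts to those
  occurring while the patient's age (``time_day / 365.25``) lies within the
  inclusive bounds.  Ages are resolved at whole-day granularity: a fact
  whose day is within half a day of the bound is kept.
* Patient-attribute conditions constrain the patient set only; their fact
  set is empty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd

from . import schema
from .errors import (
    AmbiguityError,
    ArityError,
    ConditionParseError,
    ConfigError,
    DomainError,
    SchemaVersionError,
    UnsupportedInitializationError,
)
from .schema import DatabaseHandle, FACT_COLUMNS, FactSelector

DAYS_PER_YEAR = 365.25
#: half-day slack implementing whole-day age granularity
HALF_DAY = 0.5

JSON_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class ClassSpec:
    dimension: str
    by_code: bool
    by_description: bool
    by_attribute: bool
    require_numeric: bool
    parent: str | None = None
    implicit_context: str | None = None


#: the available condition classes and how they bind to the star schema
CONDITION_CLASSES: dict[str, ClassSpec] = {
    "Diagnosis": ClassSpec("diagnosis", True, True, False, False),
    "Procedure": ClassSpec("procedure", True, True, False, False),
    "Measurement": ClassSpec("procedure", True, True, False, True, parent="Procedure"),
    "VitalSign": ClassSpec(
        "procedure", True, True, False, True, parent="Measurement", implicit_context="VITALS"
    ),
    "Material": ClassSpec("material", True, True, False, False),
    "Drug": ClassSpec("material", True, True, False, False, parent="Material",
                      implicit_context="DRUG"),
    "Encounter": ClassSpec("encounter", False, True, False, False),
    "Metadata": ClassSpec("metadata", False, True, False, False),
    "LabValue": ClassSpec("metadata", True, True, False, True),
    "Patient": ClassSpec("patient", False, True, True, False),
}

#: classes whose facts carry numeric values (legal targets of values_for)
VALUE_CLASSES = ("LabValue", "VitalSign", "Measurement")


@dataclass(frozen=True)
class ConditionNode:
    """One node of a condition tree; build with :func:`make_condition`,
    :func:`combine` and :func:`with_age` (or the class constructors and the
    ``|``/``&``/``.age`` sugar)."""

    kind: str  # "leaf" | "and" | "or"
    condition_class: str | None = None
    match_mode: str | None = None  # "by_code" | "by_description" | "by_attribute"
    context_name: str | None = None
    pattern: str | None = None
    attributes: tuple[tuple[str, object], ...] | None = None
    age_min: float | None = None
    age_max: float | None = None
    children: tuple["ConditionNode", ...] = ()

    def age(self, min_age: float | None = None, max_age: float | None = None) -> "ConditionNode":
        return with_age(self, min_age, max_age)

    def __or__(self, other: "ConditionNode") -> "ConditionNode":
        return combine("or", self, other)

    def __and__(self, other: "ConditionNode") -> "ConditionNode":
        return combine("and", self, other)


def make_condition(
    condition_class: str,
    code: str | None = None,
    context: str | None = None,
    description: str | None = None,
    attributes: Mapping[str, object] | None = None,
) -> ConditionNode:
    """Build a leaf condition; exactly one initialization mode must be used."""
    spec = _class_spec(condition_class)
    modes = [m for m, given in (
        ("by_code", code is not None),
        ("by_description", description is not None),
        ("by_attribute", attributes is not None),
    ) if given]
    if len(modes) > 1:
        raise AmbiguityError(
            f"{condition_class}: give only one of code, description, attributes"
        )
    if not modes:
        raise UnsupportedInitializationError(
            f"{condition_class}: one of code, description, attributes is required"
        )
    mode = modes[0]
    if mode == "by_code":
        if not spec.by_code:
            raise UnsupportedInitializationError(
                f"{condition_class} conditions cannot be initialized with clinical codes"
            )
        if context is None:
            raise UnsupportedInitializationError(
                f"{condition_class}: a code requires its coding context"
            )
    elif context is not None:
        raise AmbiguityError(f"{condition_class}: context only accompanies a code")
    if mode == "by_description" and not spec.by_description:
        raise UnsupportedInitializationError(
            f"{condition_class} conditions cannot be initialized with descriptions"
        )
    if mode == "by_attribute" and not spec.by_attribute:
        raise UnsupportedInitializationError(
            f"{condition_class} conditions cannot be initialized with attributes"
        )
    return ConditionNode(
        kind="leaf",
        condition_class=condition_class,
        match_mode=mode,
        context_name=context,
        pattern=code if mode == "by_code" else description,
        attributes=tuple(sorted(attributes.items())) if mode == "by_attribute" else None,
    )


def combine(op: str, *conditions: ConditionNode) -> ConditionNode:
    """AND/OR combinator over two or more conditions; nesting is arbitrary."""
    if op not in ("and", "or"):
        raise ConfigError(f"unknown Boolean operator {op!r}")
    if len(conditions) < 2:
        raise ArityError(f"{op} needs at least two operands, got {len(conditions)}")
    return ConditionNode(kind=op, children=tuple(conditions))


def with_age(
    cond: ConditionNode, min_age: float | None = None, max_age: float | None = None
) -> ConditionNode:
    """Restrict matching facts to patient ages (in years) within the
    inclusive ``[min_age, max_age]`` bounds at the time of the fact."""
    for bound in (min_age, max_age):
        if bound is not None and bound < 0:
            raise DomainError("age bounds must be non-negative")
    if min_age is not None and max_age is not None and min_age > max_age:
        raise DomainError("min_age must not exceed max_age")
    return replace(cond, age_min=min_age, age_max=max_age)


def _class_spec(name: str) -> ClassSpec:
    try:
        return CONDITION_CLASSES[name]
    except KeyError:
        raise ConfigError(f"unknown condition class {name!r}") from None


def any_of_class(condition_class: str) -> ConditionNode:
    """Match-all condition for one class (empty description substring)."""
    spec = _class_spec(condition_class)
    if spec.by_attribute and not spec.by_description:
        return make_condition(condition_class, attributes={})
    return make_condition(condition_class, description="")


def leaf_classes(cond: ConditionNode) -> frozenset[str]:
    if cond.kind == "leaf":
        return frozenset({cond.condition_class})
    out: frozenset[str] = frozenset()
    for child in cond.children:
        out |= leaf_classes(child)
    return out


# ---------------------------------------------------------------------------
# query planning


@dataclass(frozen=True)
class QueryPlan:
    """Normalized tree of per-dimension selectors mirroring the AND/OR
    structure of the condition it was compiled from."""

    op: str  # "leaf" | "and" | "or"
    selector: FactSelector | None = None
    condition_class: str | None = None
    children: tuple["QueryPlan", ...] = ()


def _age_day_bounds(
    age_min: float | None, age_max: float | None
) -> tuple[float | None, float | None]:
    lo = None if age_min is None else age_min * DAYS_PER_YEAR - HALF_DAY
    hi = None if age_max is None else age_max * DAYS_PER_YEAR + HALF_DAY
    return lo, hi


def _merge_bounds(
    inherited: tuple[float | None, float | None], node: ConditionNode
) -> tuple[float | None, float | None]:
    lo, hi = _age_day_bounds(node.age_min, node.age_max)
    ilo, ihi = inherited
    lo = ilo if lo is None else (lo if ilo is None else max(lo, ilo))
    hi = ihi if hi is None else (hi if ihi is None else min(hi, ihi))
    return lo, hi


def to_query(cond: ConditionNode) -> QueryPlan:
    """Compile a condition tree into a query plan; age filters are pushed
    down onto every leaf selector they cover."""
    return _compile(cond, (None, None))


def _compile(node: ConditionNode, bounds) -> QueryPlan:
    bounds = _merge_bounds(bounds, node)
    if node.kind != "leaf":
        return QueryPlan(op=node.kind, children=tuple(_compile(c, bounds) for c in node.children))
    spec = _class_spec(node.condition_class)
    context = node.context_name
    if context is None and node.match_mode == "by_description":
        context = spec.implicit_context
    selector = FactSelector(
        dimension=spec.dimension,
        context_name=context,
        code_pattern=node.pattern if node.match_mode == "by_code" else None,
        description_pattern=node.pattern if node.match_mode == "by_description" else None,
        require_numeric=spec.require_numeric,
        attributes=dict(node.attributes) if node.attributes is not None else (
            {} if node.match_mode == "by_attribute" else None
        ),
        min_day=bounds[0],
        max_day=bounds[1],
    )
    return QueryPlan(op="leaf", selector=selector, condition_class=node.condition_class)


# ---------------------------------------------------------------------------
# evaluation

_ROW_IDENTITY = ["dimension", "fact_key", "encounter_key", "concept_key"]


def _empty_fact_frame() -> pd.DataFrame:
    from .schema import _FACT_DTYPES

    return pd.DataFrame({c: pd.Series(dtype=d) for c, d in _FACT_DTYPES.items()})


def evaluate(cond: ConditionNode, db: DatabaseHandle) -> pd.DataFrame:
    """All fact rows matching the condition (several rows per patient are
    normal: a patient with two heart surgeries yields two rows)."""
    frame, _ = evaluate_with_patients(cond, db)
    return frame


def evaluate_with_patients(
    cond: ConditionNode, db: DatabaseHandle
) -> tuple[pd.DataFrame, set[int]]:
    """Matching fact rows plus the matched patient set.

    The patient set can be strictly larger than the patients appearing in
    the fact rows when patient-attribute conditions participate (their
    facts are defined as the empty set).
    """
    return _eval_plan(to_query(cond), db)


def _eval_plan(plan: QueryPlan, db: DatabaseHandle) -> tuple[pd.DataFrame, set[int]]:
    if plan.op == "leaf":
        if plan.selector.dimension == "patient":
            return _empty_fact_frame(), schema.fetch_patients(db, plan.selector)
        frame = schema.fetch_facts(db, plan.selector)
        return frame, set(frame["patient_key"].tolist())
    results = [_eval_plan(child, db) for child in plan.children]
    frames = [f for f, _ in results]
    if plan.op == "or":
        patients = set().union(*(p for _, p in results))
        frame = _union_rows(frames)
        return frame, patients
    patients = set.intersection(*(p for _, p in results))
    classes = [_plan_classes(child) for child in plan.children]
    same_class = all(c == classes[0] and len(c) == 1 for c in classes)
    frame = frames[0] if same_class else _union_rows(frames)
    if len(frame):
        frame = frame[frame["patient_key"].isin(patients)].reset_index(drop=True)
    return frame, patients


def _plan_classes(plan: QueryPlan) -> frozenset[str]:
    if plan.op == "leaf":
        return frozenset({plan.condition_class})
    out: frozenset[str] = frozenset()
    for child in plan.children:
        out |= _plan_classes(child)
    return out


def _union_rows(frames: Sequence[pd.DataFrame]) -> pd.DataFrame:
    nonempty = [f for f in frames if len(f)]
    if not nonempty:
        return _empty_fact_frame()
    merged = pd.concat(nonempty, ignore_index=True)
    return merged.drop_duplicates(subset=_ROW_IDENTITY).reset_index(drop=True)


# ---------------------------------------------------------------------------
# JSON (de)serialization — schema version "1", stable key order


def to_json(cond: ConditionNode) -> str:
    """Serialize a condition tree to the shareable JSON document format."""
    return json.dumps(
        {"version": JSON_SCHEMA_VERSION, "root": _node_to_dict(cond)}, indent=2
    )


def _node_to_dict(node: ConditionNode) -> dict:
    return {
        "kind": node.kind,
        "class": node.condition_class,
        "match": node.match_mode,
        "context": node.context_name,
        "pattern": node.pattern,
        "attributes": dict(node.attributes) if node.attributes is not None else None,
        "age": {"min": node.age_min, "max": node.age_max},
        "children": [_node_to_dict(c) for c in node.children],
    }


def from_json(doc: str) -> ConditionNode:
    """Parse a condition document; the inverse of :func:`to_json`."""
    try:
        data = json.loads(doc)
    except json.JSONDecodeError as exc:
        raise ConditionParseError(f"not valid JSON: {exc}") from exc
    if not isinstance(data, dict) or "root" not in data:
        raise ConditionParseError("document must be an object with a 'root' key")
    if data.get("version") != JSON_SCHEMA_VERSION:
        raise SchemaVersionError(f"unsupported document version {data.get('version')!r}")
    return _node_from_dict(data["root"])


def _node_from_dict(data: dict) -> ConditionNode:
    if not isinstance(data, dict) or "kind" not in data:
        raise ConditionParseError("condition node must be an object with a 'kind'")
    kind = data["kind"]
    if kind not in ("leaf", "and", "or"):
        raise ConditionParseError(f"unknown node kind {kind!r}")
    age = data.get("age") or {}
    if kind == "leaf":
        cls = data.get("class")
        if cls not in CONDITION_CLASSES:
            raise SchemaVersionError(f"unknown condition class {cls!r}")
        attributes = data.get("attributes")
        node = ConditionNode(
            kind="leaf",
            condition_class=cls,
            match_mode=data.get("match"),
            context_name=data.get("context"),
            pattern=data.get("pattern"),
            attributes=tuple(sorted(attributes.items())) if attributes is not None else None,
        )
        if node.match_mode not in ("by_code", "by_description", "by_attribute"):
            raise ConditionParseError(f"unknown match mode {node.match_mode!r}")
    else:
        children = data.get("children") or []
        if len(children) < 2:
            raise ConditionParseError(f"{kind} node needs at least two children")
        node = ConditionNode(kind=kind, children=tuple(_node_from_dict(c) for c in children))
    if age.get("min") is not None or age.get("max") is not None:
        node = with_age(node, age.get("min"), age.get("max"))
    return node


def save_condition(cond: ConditionNode, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(to_json(cond) + "\n")


def load_condition(path: str) -> ConditionNode:
    with open(path, encoding="utf-8") as fh:
        return from_json(fh.read())


# ---------------------------------------------------------------------------
# class-style constructors: Procedure("35.0", "ICD-9"), LabValue("GLUCOSE"),
# Patient(gender="male"), ...


def _make_constructor(name: str):
    spec = CONDITION_CLASSES[name]

    def constructor(
        arg1: str | None = None,
        arg2: str | None = None,
        *,
        code: str | None = None,
        context: str | None = None,
        description: str | None = None,
        attributes: Mapping[str, object] | None = None,
        **attrs: object,
    ) -> ConditionNode:
        if arg1 is not None and arg2 is not None:
            code, context = arg1, arg2
        elif arg1 is not None:
            # a single positional with an explicit context is a code,
            # otherwise a description (e.g. LabValue("GLUCOSE"))
            if context is not None:
                code = arg1
            else:
                description = arg1
        if attrs:
            attributes = {**(attributes or {}), **attrs}
        if code is None and description is None and attributes is None:
            # bare constructor: match every fact of the class
            return any_of_class(name)
        return make_condition(
            name, code=code, context=context, description=description, attributes=attributes
        )

    constructor.__name__ = name
    constructor.__qualname__ = name
    constructor.__doc__ = (
        f"Leaf condition of class {name} (dimension: {spec.dimension}); "
        "see make_condition for the initialization contract."
    )
    return constructor


Diagnosis = _make_constructor("Diagnosis")
Procedure = _make_constructor("Procedure")
Measurement = _make_constructor("Measurement")
VitalSign = _make_constructor("VitalSign")
Material = _make_constructor("Material")
Drug = _make_constructor("Drug")
Encounter = _make_constructor("Encounter")
Metadata = _make_constructor("Metadata")
LabValue = _make_constructor("LabValue")
Patient = _make_constructor("Patient")
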