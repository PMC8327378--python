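"""Brute-force in-memory reference evaluator.

Re-implements the documented condition semantics directly over a full
table dump with plain Python loops and sets — no SQL, no pandas joins,
independent of the library's query path.  Used to cross-check
``evaluate``/``build_cohort``/``get_pivoted_features`` row for row.
"""

from __future__ import annotations

import math
import re
import statistics

from starcohort import schema

DAYS_PER_YEAR = 365.25
HALF_DAY = 0.5

# condition-class semantics restated independently of the implementation:
# class -> (dimension, needs numeric value, implicit context for
# description matches)
CLASS_SEMANTICS = {
    "Diagnosis": ("diagnosis", False, None),
    "Procedure": ("procedure", False, None),
    "Measurement": ("procedure", True, None),
    "VitalSign": ("procedure", True, "VITALS"),
    "Material": ("material", False, None),
    "Drug": ("material", False, "DRUG"),
    "Metadata": ("metadata", False, None),
    "LabValue": ("metadata", True, None),
}


def _none(x):
    return None if x is None or (isinstance(x, float) and math.isnan(x)) else x


class WarehouseDump:
    """Plain-Python snapshot of all eight tables."""

    def __init__(self, db):
        t = schema.dump_tables(db)
        self.patients = {
            int(r["patient_key"]): dict(r) for _, r in t["d_person"].iterrows()
        }
        self.encounters = [dict(r) for _, r in t["d_encounter"].iterrows()]
        self.concepts = {}
        for dim, table in (
            ("procedure", "fd_procedure"),
            ("diagnosis", "fd_diagnosis"),
            ("material", "fd_material"),
            ("metadata", "d_metadata"),
        ):
            for _, r in t[table].iterrows():
                self.concepts[int(r["concept_key"])] = {
                    "dimension": dim,
                    "context_name": r["context_name"],
                    "code": r["code"],
                    "description": r["description"],
                }
        self.groups = {}
        for _, r in t["group_map"].iterrows():
            self.groups.setdefault(int(r["group_key"]), []).append(int(r["concept_key"]))
        self.facts = []
        for _, r in t["fact"].iterrows():
            self.facts.append({k: _none(v) for k, v in r.items()})
        self.fact_patient = {
            int(f["fact_key"]): int(f["patient_key"]) for f in self.facts
        }
        self.enc_patient = {
            int(e["encounter_key"]): int(e["patient_key"]) for e in self.encounters
        }

    def n_facts(self) -> int:
        return len(self.facts)

    def fact_concept_pairs(self, dimension: str):
        """Every (fact, member-concept) pair of one dimension — the
        join-expansion a leaf query must conserve."""
        col = f"{dimension}_group_key" if dimension != "metadata" else "metadata_key"
        for f in self.facts:
            link = f[col]
            if link is None:
                continue
            if dimension == "metadata":
                yield f, int(link)
            else:
                for ck in self.groups.get(int(link), []):
                    yield f, ck


def code_matches(pattern: str, code: str) -> bool:
    """``%`` is a multi-character wildcard; everything else is literal and
    case-sensitive; no wildcard means exact equality."""
    if "%" not in pattern:
        return code == pattern
    regex = "^" + ".*".join(re.escape(part) for part in pattern.split("%")) + "$"
    return re.match(regex, code) is not None


def _age_ok(day: int, age_min, age_max) -> bool:
    if age_min is not None and day < age_min * DAYS_PER_YEAR - HALF_DAY:
        return False
    if age_max is not None and day > age_max * DAYS_PER_YEAR + HALF_DAY:
        return False
    return True


RowId = tuple  # (dimension, fact_key, encounter_key, concept_key)


def evaluate_reference(node, dump: WarehouseDump, age_bounds=(None, None)):
    """Evaluate a condition tree over the dump.

    Returns ``(rows, patients)`` where rows is a set of row identities
    ``(dimension, fact_key, encounter_key, concept_key)`` — one per
    (fact, resolved concept) pair — and patients is the matched patient
    set (attribute conditions constrain patients without adding rows).
    """
    lo = age_bounds[0] if node.age_min is None else (
        node.age_min if age_bounds[0] is None else max(node.age_min, age_bounds[0])
    )
    hi = age_bounds[1] if node.age_max is None else (
        node.age_max if age_bounds[1] is None else min(node.age_max, age_bounds[1])
    )
    if node.kind == "leaf":
        return _leaf(node, dump, lo, hi)
    results = [evaluate_reference(c, dump, (lo, hi)) for c in node.children]
    if node.kind == "or":
        rows = set().union(*(r for r, _ in results))
        patients = set().union(*(p for _, p in results))
        return rows, patients
    patients = set.intersection(*(p for _, p in results))
    child_classes = [_classes(c) for c in node.children]
    if all(len(c) == 1 and c == child_classes[0] for c in child_classes):
        rows = results[0][0]
    else:
        rows = set().union(*(r for r, _ in results))
    rows = {r for r in rows if _row_patient(r, dump) in patients}
    return rows, patients


def _classes(node):
    if node.kind == "leaf":
        return frozenset({node.condition_class})
    out = frozenset()
    for c in node.children:
        out |= _classes(c)
    return out


def _row_patient(row: RowId, dump: WarehouseDump) -> int:
    dimension, fact_key, encounter_key, _ = row
    if dimension == "encounter":
        return dump.enc_patient[encounter_key]
    return dump.fact_patient[fact_key]


def _leaf(node, dump: WarehouseDump, age_lo, age_hi):
    cls = node.condition_class
    if cls == "Patient":
        return set(), _match_patients(node, dump)
    if cls == "Encounter":
        rows = set()
        for e in dump.encounters:
            if node.pattern is not None and node.pattern.upper() not in str(
                e["encounter_type"]
            ).upper():
                continue
            if not _age_ok(int(e["begin_day"]), age_lo, age_hi):
                continue
            rows.add(("encounter", None, int(e["encounter_key"]), None))
        return rows, {_row_patient(r, dump) for r in rows}

    dimension, needs_numeric, implicit_context = CLASS_SEMANTICS[cls]
    context = node.context_name
    if context is None and node.match_mode == "by_description":
        context = implicit_context
    rows = set()
    patients = set()
    for fact, ck in dump.fact_concept_pairs(dimension):
        concept = dump.concepts[ck]
        if context is not None and concept["context_name"] != context:
            continue
        if node.match_mode == "by_code" and not code_matches(node.pattern, concept["code"]):
            continue
        if node.match_mode == "by_description" and node.pattern.upper() not in str(
            concept["description"]
        ).upper():
            continue
        if needs_numeric and fact["numeric_value"] is None:
            continue
        if not _age_ok(int(fact["time_day"]), age_lo, age_hi):
            continue
        rows.add((dimension, int(fact["fact_key"]), int(fact["encounter_key"]), ck))
        patients.add(int(fact["patient_key"]))
    return rows, patients


def _match_patients(node, dump: WarehouseDump):
    out = set()
    for pk, p in dump.patients.items():
        if node.match_mode == "by_attribute":
            attrs = dict(node.attributes or ())
            if all(str(p.get(k)) == str(v) for k, v in attrs.items()):
                out.add(pk)
        else:
            hay = f"{p.get('gender', '')} {p.get('race') or ''}".upper()
            if (node.pattern or "").upper() in hay:
                out.add(pk)
    return out


def frame_row_ids(frame) -> set:
    """Row identities of an ``evaluate`` result frame, for comparison."""
    out = set()
    for r in frame.itertuples(index=False):
        fact_key = _none(r.fact_key)
        concept_key = _none(r.concept_key)
        out.add((
            r.dimension,
            None if fact_key is None else int(fact_key),
            int(r.encounter_key),
            None if concept_key is None else int(concept_key),
        ))
    return out


# ---------------------------------------------------------------------------
# reference cohort quantities


def reference_cohort(rows, patients, dump: WarehouseDump):
    """Members and earliest-fact anchors from a reference evaluation."""
    anchors = {pk: 0 for pk in patients}
    fact_day = {}
    for f in dump.facts:
        fact_day[int(f["fact_key"])] = (int(f["patient_key"]), int(f["time_day"]))
    enc_day = {int(e["encounter_key"]): (int(e["patient_key"]), int(e["begin_day"]))
               for e in dump.encounters}
    best = {}
    for dimension, fact_key, encounter_key, _ in rows:
        pk, day = enc_day[encounter_key] if dimension == "encounter" else fact_day[fact_key]
        if pk not in best or day < best[pk]:
            best[pk] = day
    anchors.update(best)
    return set(anchors), anchors


def reference_pivot(dump: WarehouseDump, members, anchors, config_specs):
    """Cell-for-cell reconstruction of the pivoted feature matrix.

    ``config_specs`` is a list of ``(condition_class, window, threshold,
    aggfunc names)``; returns ``{column_name: {patient_key: value}}`` with
    ``None`` for empty cells, built with plain loops and the statistics
    module.
    """
    out = {}
    for cls, window, threshold, aggfuncs in config_specs:
        dimension, needs_numeric, implicit_context = CLASS_SEMANTICS[cls]
        per_feature: dict[str, dict[int, list]] = {}
        for fact, ck in dump.fact_concept_pairs(dimension):
            pk = int(fact["patient_key"])
            if pk not in members:
                continue
            if implicit_context is not None and \
                    dump.concepts[ck]["context_name"] != implicit_context:
                continue
            if needs_numeric and fact["numeric_value"] is None:
                continue
            rel = int(fact["time_day"]) - anchors[pk]
            if not window[0] <= rel <= window[1]:
                continue
            concept = dump.concepts[ck]
            fid = (
                f"{concept['context_name']}:{concept['code']}"
                if concept["code"] is not None
                else str(concept["description"]).strip().upper()
            )
            per_feature.setdefault(fid, {}).setdefault(pk, []).append(
                (int(fact["time_day"]), fact["numeric_value"])
            )
        n = len(members)
        for fid in sorted(per_feature):
            coverage = len(per_feature[fid]) / n
            if coverage < threshold:
                continue
            for func in aggfuncs:
                col = f"{cls}__{fid}__{func}"
                cells = {pk: None for pk in members}
                for pk, pairs in per_feature[fid].items():
                    values = [v for _, v in sorted(pairs)]
                    cells[pk] = _reference_agg(values, func)
                out[col] = cells
    return out


def _reference_agg(values, func):
    if func == "count":
        return len(values)
    if func == "any":
        return 1
    if func == "min":
        return min(values)
    if func == "max":
        return max(values)
    if func == "mean":
        return statistics.fmean(values)
    if func == "median":
        return statistics.median(values)
    raise ValueError(func)


def reference_paa(series, n_segments):
    """Fractional-frame PAA by direct overlap-weight summation."""
    n = len(series)
    seg = n / n_segments
    out = []
    for i in range(n_segments):
        lo, hi = i * seg, (i + 1) * seg
        total = 0.0
        for j, x in enumerate(series):
            overlap = min(j + 1, hi) - max(j, lo)
            if overlap > 0:
                total += overlap * x
        out.append(total / seg)
    return out
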