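"""Pivoted feature extraction: from long fact rows to a wide, patient-level
modeling-ready matrix.

The central entry point is :func:`get_pivoted_features`.  For every
condition class listed in a :class:`PivotConfig` it

1. collects all in-window facts of that class for the cohort,
2. keeps only features observed for at least a *coverage threshold*
   fraction of cohort patients (sparse features are dropped, not imputed),
3. aggregates each patient's in-window values per feature with the
   configured aggregation functions.

Value-bearing classes (labs, vitals, measurements) support ``min``,
``max``, ``mean``, ``median``, ``count``, ``any`` and user-supplied
reducers; value-less classes (diagnoses, procedures, drugs/materials,
encounters, metadata) support only ``count`` and ``any`` — the standard
0/1 occurrence encoding of phenotyping pipelines.

Cells are ``null`` exactly when the patient has no in-window fact for the
feature; missing-value handling is left to downstream modeling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import conditions
from .cohort import Cohort, feature_identity
from .conditions import CONDITION_CLASSES, VALUE_CLASSES, any_of_class
from .errors import ConfigError, DomainError
from .schema import DatabaseHandle

#: aggregations legal for classes whose facts carry no numeric value
BINARY_AGGFUNCS = ("count", "any")
#: predefined aggregations for value-bearing classes
VALUE_AGGFUNCS = ("min", "max", "mean", "median", "count", "any")

AggFunc = str | Callable[[Sequence[float]], float]


@dataclass(frozen=True)
class ClassPivotSpec:
    """Extraction spec for one condition class."""

    window: tuple[int, int]
    threshold: float
    aggfuncs: tuple[AggFunc, ...]


@dataclass
class PivotConfig:
    """Ordered map ``condition_class -> ClassPivotSpec``.

    Built from a plain mapping like the one a config file would hold::

        PivotConfig({
            "LabValue": {"timewindow": [-180, 0], "threshold": 0.5,
                         "aggfuncs": ["min", "median", "max"]},
            "Diagnosis": {"timewindow": [-1825, -1], "threshold": 0.05,
                          "aggfuncs": ["any"]},
        })
    """

    specs: dict[str, ClassPivotSpec] = field(default_factory=dict)

    def __init__(self, raw: Mapping[str, Mapping] | None = None):
        self.specs = {}
        for cls, spec in (raw or {}).items():
            self.add(
                cls,
                window=tuple(spec["timewindow"]),
                threshold=spec.get("threshold", 0.0),
                aggfuncs=tuple(spec.get("aggfuncs", ("count", "any"))),
            )

    def add(
        self,
        condition_class: str,
        window: tuple[int, int],
        threshold: float,
        aggfuncs: Sequence[AggFunc],
    ) -> "PivotConfig":
        if condition_class not in CONDITION_CLASSES:
            raise ConfigError(f"unknown condition class {condition_class!r}")
        if condition_class == "Patient":
            raise ConfigError("Patient conditions carry no facts to pivot")
        a, b = window
        if a > b:
            raise ConfigError(f"{condition_class}: window start {a} exceeds end {b}")
        if not 0.0 <= threshold <= 1.0:
            raise ConfigError(f"{condition_class}: threshold {threshold} outside [0, 1]")
        if not aggfuncs:
            raise ConfigError(f"{condition_class}: at least one aggregation is required")
        value_class = condition_class in VALUE_CLASSES
        for func in aggfuncs:
            if callable(func):
                if not value_class:
                    raise ConfigError(
                        f"{condition_class}: user reducers need numeric values"
                    )
                continue
            legal = VALUE_AGGFUNCS if value_class else BINARY_AGGFUNCS
            if func not in legal:
                raise ConfigError(
                    f"{condition_class}: aggregation {func!r} not legal for this class "
                    f"(allowed: {legal})"
                )
        self.specs[condition_class] = ClassPivotSpec(
            window=(int(a), int(b)), threshold=float(threshold), aggfuncs=tuple(aggfuncs)
        )
        return self


def aggregate_series(values: Sequence[float], func: AggFunc):
    """Apply one aggregation to a patient's in-window values.

    ``values`` must already be sorted by fact time (the contract seen by
    user-supplied reducers).  An empty list yields ``None`` — a null cell,
    not an exception.
    """
    values = list(values)
    if not values:
        return None
    if callable(func):
        return func(values)
    if func == "count":
        return len(values)
    if func == "any":
        return 1
    if func == "min":
        return min(values)
    if func == "max":
        return max(values)
    if func == "mean":
        return float(np.mean(values))
    if func == "median":
        return float(np.median(values))
    raise ConfigError(f"unknown aggregation {func!r}")


def _aggfunc_name(func: AggFunc) -> str:
    return func if isinstance(func, str) else func.__name__


def _class_facts(
    c: Cohort, condition_class: str, window: tuple[int, int], db: DatabaseHandle
) -> pd.DataFrame:
    """All of the cohort's facts of one class with relative days in the
    closed window, tagged with their feature identity."""
    facts = conditions.evaluate(any_of_class(condition_class), db)
    if not len(facts):
        return facts.assign(rel_day=pd.Series(dtype=int), feature_id=pd.Series(dtype=str))
    facts = facts[facts["patient_key"].isin(c.members)].copy()
    anchors = facts["patient_key"].map(c.anchors)
    facts["rel_day"] = facts["time_day"] - anchors
    facts = facts[(facts["rel_day"] >= window[0]) & (facts["rel_day"] <= window[1])]
    facts["feature_id"] = [
        feature_identity(ctx, code, desc)
        for ctx, code, desc in facts[["context_name", "code", "description"]].itertuples(
            index=False
        )
    ]
    return facts


def feature_coverage(
    c: Cohort, condition_class: str, window: tuple[int, int], db: DatabaseHandle
) -> pd.DataFrame:
    """Fraction of cohort patients with ≥1 in-window fact, per feature.

    Coverage counts distinct patients, not facts.  Every feature with at
    least one hit is listed.  Raises on an empty cohort (the fraction is
    undefined).
    """
    if not len(c.members):
        raise DomainError("coverage is undefined for an empty cohort")
    facts = _class_facts(c, condition_class, window, db)
    if not len(facts):
        return pd.DataFrame(columns=["feature_id", "coverage"])
    cov = (
        facts.groupby("feature_id")["patient_key"].nunique() / len(c.members)
    ).rename("coverage")
    return cov.reset_index().sort_values("feature_id").reset_index(drop=True)


def get_pivoted_features(
    c: Cohort, config: PivotConfig, db: DatabaseHandle
) -> pd.DataFrame:
    """The wide feature matrix: one row per cohort member, one column per
    surviving (class, feature, aggregation) triple.

    Columns are named ``<class>__<feature_id>__<aggfunc>`` and ordered by
    class order in the config, then feature id, then aggfunc order.
    Features below their class threshold are dropped (ties at the
    threshold are kept).  Cells are null exactly when the patient has no
    in-window fact for the feature.
    """
    if not config.specs:
        raise ConfigError("pivot config lists no condition classes")
    if not len(c.members):
        raise DomainError("cannot pivot an empty cohort")
    index = sorted(c.members)
    columns: dict[str, pd.Series] = {}
    meta: dict[str, dict] = {}
    for cls, spec in config.specs.items():
        facts = _class_facts(c, cls, spec.window, db)
        if not len(facts):
            continue
        cov = facts.groupby("feature_id")["patient_key"].nunique() / len(c.members)
        keep = sorted(cov[cov >= spec.threshold].index)
        facts = facts[facts["feature_id"].isin(keep)].sort_values("time_day", kind="stable")
        value_class = cls in VALUE_CLASSES
        grouped = facts.groupby(["feature_id", "patient_key"])
        series = grouped["numeric_value"].agg(list) if value_class else grouped.size()
        for fid in keep:
            fid_values = series.loc[fid] if fid in series.index.get_level_values(0) else {}
            detail = facts[facts["feature_id"] == fid].iloc[0]
            for func in spec.aggfuncs:
                name = f"{cls}__{fid}__{_aggfunc_name(func)}"
                cells = {}
                for pk in index:
                    if pk in fid_values:
                        if value_class:
                            cells[pk] = aggregate_series(fid_values[pk], func)
                        else:
                            n = int(fid_values[pk])
                            cells[pk] = n if func == "count" else 1
                    else:
                        cells[pk] = None
                columns[name] = pd.Series(cells, dtype=object)
                meta[name] = {
                    "condition_class": cls,
                    "feature_id": fid,
                    "context_name": None if pd.isna(detail["context_name"]) else detail["context_name"],
                    "code": None if pd.isna(detail["code"]) else detail["code"],
                    "description": detail["description"],
                    "aggfunc": _aggfunc_name(func),
                    "coverage": float(cov[fid]),
                    "window": list(spec.window),
                }
    converted = {
        name: (col.astype(float) if _is_numericable(col) else col)
        for name, col in columns.items()
    }
    matrix = pd.DataFrame(converted, index=pd.Index(index, name="patient_key"))
    matrix.attrs["column_meta"] = meta
    return matrix


def _is_numericable(col: pd.Series) -> bool:
    return all(v is None or isinstance(v, (int, float, np.integer, np.floating)) for v in col)


def save_feature_matrix(matrix: pd.DataFrame, path: str) -> None:
    """Write the matrix as CSV (or Parquet when the path ends ``.parquet``)
    plus a ``<path>.meta.json`` sidecar of per-column metadata."""
    if path.endswith(".parquet"):
        matrix.reset_index().to_parquet(path, index=False)
    else:
        matrix.to_csv(path, index=True)
    meta = matrix.attrs.get("column_meta", {})
    with open(f"{path}.meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
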