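"""Cohorts: patient sets admitted by a condition, anchored in time.

A cohort is the set of patients with at least one matching occurrence of
its defining condition.  Each member gets exactly one *anchor day* — the
earliest matching fact — which aligns the member's timeline for
everything downstream: onset labels, occurrence counts, value series and
feature windows are all expressed in days relative to the anchor.

Two conventions matter and are deliberate:

* The anchor is the **earliest** matching fact (the standard index-event
  convention).  Members admitted purely by patient-attribute conditions
  have no matching facts; their anchor is day 0 (birth).
* Onset is **strictly after** the anchor day: an outcome coded on the
  anchor day itself is treated as pre-existing, not as onset.  Windows are
  closed intervals of relative days, so ``[-180, 0]`` includes the anchor
  day itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import conditions, schema
from .conditions import ConditionNode, DAYS_PER_YEAR, leaf_classes
from .errors import ClassMismatchError, DomainError
from .schema import DatabaseHandle, GENDERS


def feature_identity(context_name, code, description) -> str:
    """Stable feature key: ``context:code`` when coded, else the
    uppercased description (distinct codes never merge on a shared name)."""
    if code is not None and not (isinstance(code, float) and np.isnan(code)):
        return f"{context_name}:{code}"
    return str(description).strip().upper()


@dataclass
class Cohort:
    """Patient set + per-patient anchor days for one condition."""

    definition: ConditionNode | None
    db: DatabaseHandle
    members: frozenset[int]
    anchors: dict[int, int]
    mrns: dict[int, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        keys = sorted(self.members)
        return pd.DataFrame(
            {
                "patient_key": keys,
                "mrn": [self.mrns.get(k, "") for k in keys],
                "anchor_day": [self.anchors[k] for k in keys],
            }
        )

    def save(self, prefix: str) -> None:
        """Write the member/anchor table as ``<prefix>_members.csv`` and
        ``<prefix>_members.parquet``."""
        frame = self.to_frame()
        frame.to_csv(f"{prefix}_members.csv", index=False)
        frame.to_parquet(f"{prefix}_members.parquet", index=False)


@dataclass
class OnsetLabel:
    """Binary outcome labels for every cohort member."""

    name: str
    labels: dict[int, int]
    window_days: int | None

    def to_frame(self) -> pd.DataFrame:
        keys = sorted(self.labels)
        return pd.DataFrame(
            {"patient_key": keys, self.name: [self.labels[k] for k in keys]}
        )

    def save(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


def build_cohort(cond: ConditionNode, db: DatabaseHandle) -> Cohort:
    """Evaluate the condition and assemble members and anchors.

    Members are the patients with ≥1 matching occurrence; the anchor is
    the minimum ``time_day`` over the member's matching facts (day 0 for
    purely attribute-matched members).  An empty cohort is legal.
    """
    facts, patients = conditions.evaluate_with_patients(cond, db)
    anchors: dict[int, int] = {p: 0 for p in patients}
    mrns: dict[int, str] = {}
    if len(facts):
        first = facts.groupby("patient_key")["time_day"].min()
        for key, day in first.items():
            anchors[int(key)] = int(day)
        for key, mrn in facts.drop_duplicates("patient_key")[
            ["patient_key", "mrn"]
        ].itertuples(index=False):
            mrns[int(key)] = mrn
    return Cohort(
        definition=cond,
        db=db,
        members=frozenset(anchors),
        anchors=anchors,
        mrns=mrns,
    )


def cohort_from_frame(db: DatabaseHandle, frame: pd.DataFrame) -> Cohort:
    """Rebuild a cohort from a saved member/anchor table."""
    anchors = {int(r.patient_key): int(r.anchor_day) for r in frame.itertuples(index=False)}
    mrns = (
        {int(r.patient_key): str(r.mrn) for r in frame.itertuples(index=False)}
        if "mrn" in frame.columns
        else {}
    )
    return Cohort(definition=None, db=db, members=frozenset(anchors), anchors=anchors, mrns=mrns)


def demographics(c: Cohort) -> pd.DataFrame:
    """Cohort size and age-at-anchor summary, partitioned by gender.

    Ages are anchor ages in years (days / 365.25).  An empty cohort yields
    a table of zero counts with undefined (NaN) ages.
    """
    rows = []
    genders = _member_genders(c)
    for gender in GENDERS + ("total",):
        if gender == "total":
            keys = list(c.members)
        else:
            keys = [k for k in c.members if genders.get(k) == gender]
        ages = np.array([c.anchors[k] for k in keys], dtype=float) / DAYS_PER_YEAR
        rows.append(
            {
                "gender": gender,
                "count": len(keys),
                "mean_age_years": float(np.mean(ages)) if len(ages) else np.nan,
                "std_age_years": float(np.std(ages)) if len(ages) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _member_genders(c: Cohort) -> dict[int, str]:
    if not c.members:
        return {}
    with c.db.connect() as conn:
        rows = conn.execute("SELECT patient_key, gender FROM d_person").fetchall()
    return {k: g for k, g in rows if k in c.members}


def has_onset(
    c: Cohort, name: str, cond: ConditionNode, window_days: int | None = None
) -> OnsetLabel:
    """Label members 1 when the condition occurs strictly after their
    anchor (and within ``window_days`` relative days when bounded)."""
    if window_days is not None and window_days <= 0:
        raise DomainError("window_days must be positive (or None for unbounded)")
    facts = conditions.evaluate(cond, c.db)
    labels = {k: 0 for k in c.members}
    if len(facts):
        facts = facts[facts["patient_key"].isin(c.members)]
        for key, day in facts[["patient_key", "time_day"]].itertuples(index=False):
            anchor = c.anchors[int(key)]
            rel = int(day) - anchor
            if rel > 0 and (window_days is None or rel <= window_days):
                labels[int(key)] = 1
    return OnsetLabel(name=name, labels=labels, window_days=window_days)


def _check_window(window) -> tuple[int, int] | None:
    if window is None:
        return None
    a, b = window
    if a > b:
        raise DomainError(f"window start {a} exceeds end {b}")
    return (a, b)


def occurs(
    c: Cohort, cond: ConditionNode, window: tuple[int, int] | None = None
) -> pd.DataFrame:
    """Occurrence indicator and count of the condition per member, counted
    over relative days in the closed window (all time when ``None``)."""
    window = _check_window(window)
    facts = conditions.evaluate(cond, c.db)
    counts = {k: 0 for k in c.members}
    if len(facts):
        facts = facts[facts["patient_key"].isin(c.members)]
        for key, day in facts[["patient_key", "time_day"]].itertuples(index=False):
            rel = int(day) - c.anchors[int(key)]
            if window is None or window[0] <= rel <= window[1]:
                counts[int(key)] += 1
    keys = sorted(c.members)
    return pd.DataFrame(
        {
            "patient_key": keys,
            "occurred": [int(counts[k] > 0) for k in keys],
            "n_occurrences": [counts[k] for k in keys],
        }
    )


VALUE_SERIES_COLUMNS = ["patient_key", "time_day", "rel_day", "feature_id", "numeric_value", "unit"]


def values_for(
    c: Cohort, cond: ConditionNode, window: tuple[int, int] | None = None
) -> pd.DataFrame:
    """Long value series for a value-bearing condition (labs, vitals,
    measurements): one row per matching numeric fact inside the window."""
    bad = leaf_classes(cond) - set(conditions.VALUE_CLASSES)
    if bad:
        raise ClassMismatchError(
            f"values_for needs value-bearing condition classes, got {sorted(bad)}"
        )
    window = _check_window(window)
    facts = conditions.evaluate(cond, c.db)
    if not len(facts):
        return pd.DataFrame(columns=VALUE_SERIES_COLUMNS)
    facts = facts[facts["patient_key"].isin(c.members) & facts["numeric_value"].notna()].copy()
    facts["rel_day"] = facts.apply(
        lambda r: int(r["time_day"]) - c.anchors[int(r["patient_key"])], axis=1
    )
    if window is not None:
        facts = facts[(facts["rel_day"] >= window[0]) & (facts["rel_day"] <= window[1])]
    facts["feature_id"] = [
        feature_identity(ctx, code, desc)
        for ctx, code, desc in facts[["context_name", "code", "description"]].itertuples(
            index=False
        )
    ]
    return facts[VALUE_SERIES_COLUMNS].reset_index(drop=True)
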