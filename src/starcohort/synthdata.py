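"""Synthetic star-schema warehouse generator with exported ground truth.

The generator emulates a deidentified clinical data warehouse at desk
scale: patients carry private day-offset timelines, encounters arrive as
a base process with a burst around an *anchor* event (heart surgery,
ICD-9-style procedure codes under ``35.`` / ``36.1``), anchors are
probabilistically followed by an *outcome* event (acute kidney injury,
``584.x``), and sparse irregular laboratory panels and vital signs hang
off the encounters.  Every stochastic choice is recorded in a
:class:`GroundTruth` document so the full query stack can be checked
against what was planted, with zero tolerance.

Reproducibility: all draws come from one seeded ``numpy`` generator with
a fixed per-patient draw order (gender, race, deceased flag, age,
anchor, outcome, encounters, coded events, lab offsets, per-encounter
panels, vitals).  The same seed yields a byte-identical ground-truth
document and row-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import schema
from .conditions import DAYS_PER_YEAR, HALF_DAY
from .errors import ConfigError
from .schema import DatabaseHandle, create_schema, insert_rows


@dataclass(frozen=True)
class NumericConcept:
    """A lab test or vital sign: sampling prevalence per panel and a
    patient-shifted Gaussian value model."""

    code: str
    description: str
    prevalence: float
    mean: float
    sd: float
    between_sd: float
    unit: str
    context: str = "LAB"
    dimension: str = "metadata"


@dataclass(frozen=True)
class CodedConcept:
    """A coded event (diagnosis / material / procedure) with a per-patient
    lifetime prevalence and 1–`max_occurrences` occurrences when present."""

    dimension: str
    context: str
    code: str
    description: str
    prevalence: float
    max_occurrences: int = 2


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; see :func:`default_heart_surgery_config` for
    the shipped study conditions."""

    seed: int
    n_patients: int
    gender_probs: tuple[tuple[str, float], ...] = (("male", 0.6), ("female", 0.4))
    race_probs: tuple[tuple[str, float], ...] = (
        ("WHITE", 0.4), ("BLACK", 0.2), ("HISPANIC", 0.2), ("ASIAN", 0.1), ("OTHER", 0.1)
    )
    age_mean_years: float = 60.0
    age_sd_years: float = 15.0
    followup_days: int = 730
    base_encounter_rate_per_year: float = 4.0
    burst_multiplier: float = 4.0
    burst_halfwidth_days: int = 30
    encounter_type_probs: tuple[tuple[str, float], ...] = (
        ("outpatient", 0.6), ("inpatient", 0.3), ("emergency", 0.1)
    )
    concepts: tuple[CodedConcept, ...] = ()
    labs: tuple[NumericConcept, ...] = ()
    vitals: tuple[NumericConcept, ...] = ()
    anchor_concepts: tuple[tuple[str, str, str], ...] = ()  # (context, code, description)
    anchor_prevalence: float = 0.0
    anchor_min_age_years: float = 18.0
    outcome_concepts: tuple[tuple[str, str, str], ...] = ()
    p_onset_7d: float = 0.0
    p_onset_8_28d: float = 0.0
    p_background_outcome: float = 0.0
    lab_panel_rate: float = 0.6
    vital_rate: float = 0.7
    group_prob: float = 0.15
    signal_lab_code: str | None = None
    signal_shift: float = 0.0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be non-negative")
        probs = [
            self.anchor_prevalence, self.p_onset_7d, self.p_onset_8_28d,
            self.p_background_outcome, self.lab_panel_rate, self.vital_rate,
            self.group_prob,
        ]
        probs += [p for _, p in self.gender_probs]
        probs += [c.prevalence for c in self.concepts]
        probs += [c.prevalence for c in self.labs + self.vitals]
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if abs(sum(p for _, p in self.gender_probs) - 1.0) > 1e-9:
            raise ConfigError("gender probabilities must sum to 1")
        if self.p_onset_7d + self.p_onset_8_28d > 1.0:
            raise ConfigError("onset probabilities sum above 1")
        if self.anchor_prevalence > 0 and not self.anchor_concepts:
            raise ConfigError("anchor prevalence set but no anchor concepts given")
        if self.followup_days < 200:
            raise ConfigError("followup_days must be at least 200")

    def to_json(self) -> str:
        def enc(obj):
            if isinstance(obj, (NumericConcept, CodedConcept)):
                return {"__type__": type(obj).__name__, **obj.__dict__}
            raise TypeError(type(obj))

        return json.dumps(self.__dict__, default=enc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, doc: str) -> "SynthConfig":
        def dec(d: dict):
            kind = d.pop("__type__", None)
            if kind == "NumericConcept":
                return NumericConcept(**d)
            if kind == "CodedConcept":
                return CodedConcept(**d)
            return d

        try:
            data = json.loads(doc, object_hook=dec)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config is not valid JSON: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError("config document must be a JSON object")
        try:
            data = {
                k: tuple(tuple(x) if isinstance(x, list) else x for x in v)
                if isinstance(v, list) else v
                for k, v in data.items()
            }
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(f"bad config field: {exc}") from exc


@dataclass
class GroundTruth:
    """Planted per-patient truth: demographics, anchor/outcome days,
    every coded event, and every numeric draw."""

    seed: int
    n_patients: int
    patients: dict[int, dict] = field(default_factory=dict)

    def anchor_patients(self) -> dict[int, int]:
        return {
            pk: p["anchor_day"] for pk, p in self.patients.items()
            if p["anchor_day"] is not None
        }

    def onset_labels(self, window_days: int | None) -> dict[int, int]:
        """Labels re-derived from the planted event list: 1 iff an outcome
        event falls strictly after the anchor and within the window."""
        labels = {}
        for pk, anchor in self.anchor_patients().items():
            days = self.patients[pk]["outcome_days"]
            labels[pk] = int(any(
                d > anchor and (window_days is None or d - anchor <= window_days)
                for d in days
            ))
        return labels

    def to_json(self) -> str:
        doc = {
            "seed": self.seed,
            "n_patients": self.n_patients,
            "patients": {str(k): v for k, v in sorted(self.patients.items())},
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json() + "\n")


def _min_anchor_day(min_age_years: float) -> int:
    # smallest integer day the age filter retains (half-day rounding)
    return int(np.ceil(min_age_years * DAYS_PER_YEAR - HALF_DAY))


def generate(config: SynthConfig, target: str) -> tuple[DatabaseHandle, GroundTruth]:
    """Generate a full warehouse at ``target`` plus its ground truth.

    The database passes :func:`starcohort.schema.validate` with zero
    violations by construction; an invalid config raises before any
    writes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    db = create_schema(target)

    builder = _Builder(config)
    truth = GroundTruth(seed=config.seed, n_patients=config.n_patients)
    for patient_key in range(1, config.n_patients + 1):
        truth.patients[patient_key] = builder.simulate_patient(patient_key, rng)
    builder.flush(db)
    return db, truth


class _Builder:
    """Accumulates table rows while one patient at a time is simulated."""

    def __init__(self, cfg: SynthConfig):
        self.cfg = cfg
        self.persons: list[tuple] = []
        self.encounters: list[tuple] = []
        self.facts: list[tuple] = []
        self.group_rows: list[tuple] = []
        self._encounter_key = 0
        self._fact_key = 0
        self._group_key = 0
        self._singleton_groups: dict[int, int] = {}
        self._multi_groups: dict[frozenset[int], int] = {}
        self._register_concepts()

    def _register_concepts(self) -> None:
        cfg = self.cfg
        self.concept_rows: dict[str, list[tuple]] = {d: [] for d in schema.DIMENSIONS}
        self.concept_keys: dict[tuple[str, str, str], int] = {}
        key = 0

        def add(dimension: str, context: str, code: str, description: str) -> int:
            nonlocal key
            ident = (dimension, context, code)
            if ident in self.concept_keys:
                return self.concept_keys[ident]
            key += 1
            self.concept_keys[ident] = key
            self.concept_rows[dimension].append((key, context, code, description.upper()))
            return key

        for ctx, code, desc in cfg.anchor_concepts:
            add("procedure", ctx, code, desc)
        for ctx, code, desc in cfg.outcome_concepts:
            add("diagnosis", ctx, code, desc)
        for c in cfg.concepts:
            add(c.dimension, c.context, c.code, c.description)
        for c in cfg.labs + cfg.vitals:
            add(c.dimension, c.context, c.code, c.description)

    # -- key allocation ----------------------------------------------------

    def _group_for(self, concept_keys: frozenset[int]) -> int:
        if len(concept_keys) == 1:
            (ck,) = concept_keys
            if ck not in self._singleton_groups:
                self._group_key += 1
                self._singleton_groups[ck] = self._group_key
                self.group_rows.append((self._group_key, ck))
            return self._singleton_groups[ck]
        if concept_keys not in self._multi_groups:
            self._group_key += 1
            self._multi_groups[concept_keys] = self._group_key
            for ck in sorted(concept_keys):
                self.group_rows.append((self._group_key, ck))
        return self._multi_groups[concept_keys]

    def _add_fact(self, patient_key: int, encounter_key: int, dimension: str,
                  concept_keys: frozenset[int], day: int,
                  value: float | None = None, unit: str | None = None) -> None:
        self._fact_key += 1
        links = {d: None for d in ("procedure", "diagnosis", "material")}
        metadata_key = None
        if dimension == "metadata":
            (metadata_key,) = concept_keys
        else:
            links[dimension] = self._group_for(concept_keys)
        self.facts.append((
            self._fact_key, patient_key, encounter_key,
            links["procedure"], links["diagnosis"], links["material"],
            metadata_key, int(day), value, None, unit,
        ))

    # -- simulation --------------------------------------------------------

    def simulate_patient(self, patient_key: int, rng: np.random.Generator) -> dict:
        cfg = self.cfg
        gender = _choice(rng, cfg.gender_probs)
        race = _choice(rng, cfg.race_probs)
        deceased = int(rng.random() < 0.08)
        age_first = max(1.0, rng.normal(cfg.age_mean_years, cfg.age_sd_years))
        day0 = int(round(age_first * DAYS_PER_YEAR))
        day_end = day0 + cfg.followup_days
        self.persons.append(
            (patient_key, f"MRN{patient_key:07d}", gender, 0, race, deceased)
        )

        # anchor event
        anchor_day = None
        anchor_concept = None
        if rng.random() < cfg.anchor_prevalence and cfg.anchor_concepts:
            lo = max(day0 + 60, _min_anchor_day(cfg.anchor_min_age_years))
            hi = day_end - 60
            if lo <= hi:
                anchor_day = int(rng.integers(lo, hi + 1))
                anchor_concept = cfg.anchor_concepts[
                    int(rng.integers(0, len(cfg.anchor_concepts)))
                ]

        # outcome event(s)
        outcome_days: list[int] = []
        u = rng.random()
        if anchor_day is not None:
            if u < cfg.p_onset_7d:
                outcome_days = [anchor_day + int(rng.integers(1, 8))]
            elif u < cfg.p_onset_7d + cfg.p_onset_8_28d:
                outcome_days = [anchor_day + int(rng.integers(8, 29))]
        elif u < cfg.p_background_outcome:
            outcome_days = [int(rng.integers(day0, day_end))]

        # encounter days: base process plus a burst around the anchor
        n_base = rng.poisson(
            cfg.base_encounter_rate_per_year * cfg.followup_days / DAYS_PER_YEAR
        )
        days = set(int(d) for d in rng.integers(day0, day_end, size=n_base))
        if anchor_day is not None:
            days.add(anchor_day)
            halfwidth = cfg.burst_halfwidth_days
            extra = rng.poisson(
                cfg.base_encounter_rate_per_year * (cfg.burst_multiplier - 1.0)
                * (2 * halfwidth + 1) / DAYS_PER_YEAR
            )
            burst = rng.integers(anchor_day - halfwidth, anchor_day + halfwidth + 1,
                                 size=extra)
            days.update(int(d) for d in np.clip(burst, day0, day_end - 1))
        days.update(outcome_days)
        enc_days = sorted(days)
        enc_keys: dict[int, int] = {}
        for day in enc_days:
            self._encounter_key += 1
            enc_type = _choice(rng, cfg.encounter_type_probs)
            duration = int(rng.integers(0, 6)) if enc_type == "inpatient" else 0
            self.encounters.append(
                (self._encounter_key, patient_key, enc_type, day, day + duration)
            )
            enc_keys[day] = self._encounter_key

        events: list[dict] = []

        def record(dimension: str, concept: tuple[str, str, str], day: int) -> None:
            ctx, code, desc = concept
            events.append({"dimension": dimension, "context": ctx, "code": code,
                           "day": int(day)})

        if anchor_day is not None:
            ck = self.concept_keys[("procedure",) + anchor_concept[:2]]
            self._add_fact(patient_key, enc_keys[anchor_day], "procedure",
                           frozenset({ck}), anchor_day)
            record("procedure", anchor_concept, anchor_day)
        for day in outcome_days:
            concept = cfg.outcome_concepts[int(rng.integers(0, len(cfg.outcome_concepts)))]
            ck = self.concept_keys[("diagnosis",) + concept[:2]]
            self._add_fact(patient_key, enc_keys[day], "diagnosis",
                           frozenset({ck}), day)
            record("diagnosis", concept, day)

        # coded background events, possibly grouped within an encounter
        pending: dict[tuple[int, str], list[int]] = {}
        if enc_days:
            hits = rng.random(len(cfg.concepts))
            for concept, h in zip(cfg.concepts, hits):
                if h >= concept.prevalence:
                    continue
                n_occ = int(rng.integers(1, concept.max_occurrences + 1))
                occ_days = rng.choice(enc_days, size=min(n_occ, len(enc_days)),
                                      replace=False)
                ck = self.concept_keys[(concept.dimension, concept.context, concept.code)]
                for day in sorted(int(d) for d in occ_days):
                    if concept.dimension in ("diagnosis", "material"):
                        pending.setdefault((day, concept.dimension), []).append(ck)
                    else:
                        self._add_fact(patient_key, enc_keys[day], concept.dimension,
                                       frozenset({ck}), day)
                    record(concept.dimension, (concept.context, concept.code,
                                               concept.description), day)
        for (day, dimension), cks in sorted(pending.items()):
            if len(cks) >= 2 and rng.random() < cfg.group_prob:
                self._add_fact(patient_key, enc_keys[day], dimension,
                               frozenset(cks), day)
            else:
                for ck in cks:
                    self._add_fact(patient_key, enc_keys[day], dimension,
                                   frozenset({ck}), day)

        # numeric draws: labs gated per-encounter by the panel rate, vitals not
        draws: dict[str, list[list]] = {}
        shifted = anchor_day is not None and bool(outcome_days)
        if enc_days:
            offsets = {
                c.code: rng.normal(0.0, c.between_sd)
                for c in self.cfg.labs + self.cfg.vitals
            }
            panel = rng.random(len(enc_days)) < cfg.lab_panel_rate
            for i, day in enumerate(enc_days):
                for c in cfg.labs:
                    if panel[i] and rng.random() < c.prevalence:
                        self._numeric_fact(patient_key, enc_keys[day], c, day,
                                           offsets[c.code], shifted, rng, draws)
                for c in cfg.vitals:
                    if rng.random() < cfg.vital_rate * c.prevalence:
                        self._numeric_fact(patient_key, enc_keys[day], c, day,
                                           offsets[c.code], shifted, rng, draws)

        labels: dict[str, int | None] = {"label_7": None, "label_28": None}
        if anchor_day is not None:
            for w, name in ((7, "label_7"), (28, "label_28")):
                labels[name] = int(any(
                    d > anchor_day and d - anchor_day <= w for d in outcome_days
                ))
        return {
            "mrn": f"MRN{patient_key:07d}",
            "gender": gender,
            "race": race,
            "deceased": deceased,
            "first_day": day0,
            "last_day": day_end,
            "anchor_day": anchor_day,
            "outcome_days": sorted(outcome_days),
            **labels,
            "events": sorted(events, key=lambda e: (e["day"], e["dimension"], e["code"])),
            "numeric_draws": {k: sorted(v) for k, v in sorted(draws.items())},
        }

    def _numeric_fact(self, patient_key: int, encounter_key: int, c: NumericConcept,
                      day: int, offset: float, shifted: bool,
                      rng: np.random.Generator, draws: dict) -> None:
        value = c.mean + offset + rng.normal(0.0, c.sd)
        if shifted and self.cfg.signal_lab_code == c.code:
            value += self.cfg.signal_shift
        value = round(max(value, 0.01), 4)
        ck = self.concept_keys[(c.dimension, c.context, c.code)]
        self._add_fact(patient_key, encounter_key, c.dimension, frozenset({ck}),
                       day, value=value, unit=c.unit)
        draws.setdefault(c.code, []).append([int(day), value])

    def flush(self, db: DatabaseHandle) -> None:
        insert_rows(db, "d_person",
                    ("patient_key", "mrn", "gender", "birth_offset_days", "race",
                     "deceased"), self.persons)
        insert_rows(db, "d_encounter",
                    ("encounter_key", "patient_key", "encounter_type", "begin_day",
                     "end_day"), self.encounters)
        for dimension, rows in self.concept_rows.items():
            table = {"procedure": "fd_procedure", "diagnosis": "fd_diagnosis",
                     "material": "fd_material", "metadata": "d_metadata"}[dimension]
            insert_rows(db, table, ("concept_key", "context_name", "code", "description"),
                        rows)
        insert_rows(db, "group_map", ("group_key", "concept_key"), self.group_rows)
        insert_rows(db, "fact",
                    ("fact_key", "patient_key", "encounter_key", "procedure_group_key",
                     "diagnosis_group_key", "material_group_key", "metadata_key",
                     "time_day", "numeric_value", "text_value", "unit"), self.facts)


def _choice(rng: np.random.Generator, pairs: Sequence[tuple[str, float]]) -> str:
    u = rng.random()
    acc = 0.0
    for name, p in pairs:
        acc += p
        if u < acc:
            return name
    return pairs[-1][0]


# ---------------------------------------------------------------------------
# shipped study conditions: heart surgery → acute kidney injury

_LAB_PANEL = [
    # code, description, prevalence, mean, sd, between_sd, unit
    ("GLU", "GLUCOSE", 0.85, 105.0, 25.0, 10.0, "mg/dL"),
    ("CREA", "CREATININE", 0.85, 1.0, 0.25, 0.15, "mg/dL"),
    ("BUN", "BLOOD UREA NITROGEN", 0.80, 16.0, 5.0, 3.0, "mg/dL"),
    ("NA", "SODIUM", 0.80, 139.0, 3.0, 1.5, "mmol/L"),
    ("K", "POTASSIUM", 0.80, 4.1, 0.4, 0.2, "mmol/L"),
    ("CL", "CHLORIDE", 0.75, 102.0, 3.0, 1.5, "mmol/L"),
    ("CO2", "CARBON DIOXIDE", 0.75, 25.0, 2.5, 1.2, "mmol/L"),
    ("CA", "CALCIUM", 0.70, 9.3, 0.5, 0.25, "mg/dL"),
    ("HGB", "HEMOGLOBIN", 0.75, 13.5, 1.5, 0.8, "g/dL"),
    ("HCT", "HEMATOCRIT", 0.75, 40.0, 4.0, 2.0, "%"),
    ("WBC", "WHITE BLOOD CELL COUNT", 0.75, 7.5, 2.0, 1.0, "10^9/L"),
    ("PLT", "PLATELET COUNT", 0.70, 250.0, 60.0, 30.0, "10^9/L"),
    ("ALB", "ALBUMIN", 0.55, 4.0, 0.4, 0.2, "g/dL"),
    ("ALT", "ALANINE AMINOTRANSFERASE", 0.50, 28.0, 12.0, 6.0, "U/L"),
    ("AST", "ASPARTATE AMINOTRANSFERASE", 0.50, 26.0, 11.0, 5.0, "U/L"),
    ("TBIL", "TOTAL BILIRUBIN", 0.45, 0.8, 0.3, 0.15, "mg/dL"),
    ("ALP", "ALKALINE PHOSPHATASE", 0.45, 80.0, 25.0, 12.0, "U/L"),
    ("INR", "INTERNATIONAL NORMALIZED RATIO", 0.40, 1.1, 0.2, 0.1, "ratio"),
    ("PTT", "PARTIAL THROMBOPLASTIN TIME", 0.35, 30.0, 5.0, 2.5, "s"),
    ("TROP", "TROPONIN I", 0.15, 0.04, 0.03, 0.01, "ng/mL"),
    ("BNP", "B-TYPE NATRIURETIC PEPTIDE", 0.12, 150.0, 80.0, 40.0, "pg/mL"),
    ("MG", "MAGNESIUM", 0.45, 2.0, 0.25, 0.12, "mg/dL"),
    ("PHOS", "PHOSPHATE", 0.35, 3.5, 0.6, 0.3, "mg/dL"),
    ("LACT", "LACTATE", 0.12, 1.5, 0.7, 0.3, "mmol/L"),
    ("CRP", "C-REACTIVE PROTEIN", 0.18, 6.0, 5.0, 2.5, "mg/L"),
    ("TSH", "THYROID STIMULATING HORMONE", 0.20, 2.2, 1.2, 0.6, "mIU/L"),
    ("A1C", "HEMOGLOBIN A1C", 0.25, 6.0, 1.0, 0.5, "%"),
    ("LDL", "LOW DENSITY LIPOPROTEIN", 0.30, 110.0, 30.0, 15.0, "mg/dL"),
    ("HDL", "HIGH DENSITY LIPOPROTEIN", 0.30, 50.0, 12.0, 6.0, "mg/dL"),
    ("TRIG", "TRIGLYCERIDES", 0.30, 140.0, 60.0, 30.0, "mg/dL"),
]

_VITALS = [
    ("HR", "HEART RATE", 0.95, 78.0, 12.0, 5.0, "bpm"),
    ("SBP", "SYSTOLIC BLOOD PRESSURE", 0.90, 128.0, 15.0, 8.0, "mmHg"),
    ("DBP", "DIASTOLIC BLOOD PRESSURE", 0.90, 78.0, 10.0, 5.0, "mmHg"),
    ("RESP", "RESPIRATORY RATE", 0.80, 16.0, 3.0, 1.5, "breaths/min"),
    ("TEMP", "BODY TEMPERATURE", 0.80, 36.9, 0.4, 0.15, "degC"),
    ("SPO2", "OXYGEN SATURATION", 0.85, 97.0, 1.5, 0.8, "%"),
]

_DIAGNOSES = [
    ("401.9", "ESSENTIAL HYPERTENSION UNSPECIFIED", 0.45),
    ("250.00", "DIABETES MELLITUS TYPE II WITHOUT COMPLICATION", 0.25),
    ("414.01", "CORONARY ATHEROSCLEROSIS OF NATIVE CORONARY ARTERY", 0.30),
    ("428.0", "CONGESTIVE HEART FAILURE UNSPECIFIED", 0.18),
    ("585.9", "CHRONIC KIDNEY DISEASE UNSPECIFIED", 0.10),
    ("272.4", "HYPERLIPIDEMIA UNSPECIFIED", 0.35),
    ("427.31", "ATRIAL FIBRILLATION", 0.15),
    ("493.90", "ASTHMA UNSPECIFIED", 0.08),
    ("530.81", "ESOPHAGEAL REFLUX", 0.20),
]

_DRUGS = [
    ("FURO", "FUROSEMIDE", 0.22),
    ("ASA", "ASPIRIN", 0.40),
    ("METO", "METOPROLOL", 0.30),
    ("HEP", "HEPARIN", 0.18),
    ("INS", "INSULIN", 0.15),
    ("ATOR", "ATORVASTATIN", 0.32),
]

_EXTRA_PROCEDURES = [
    ("47.09", "OTHER APPENDECTOMY", 0.04),
    ("81.54", "TOTAL KNEE REPLACEMENT", 0.05),
    ("45.23", "COLONOSCOPY", 0.15),
]

_ANCHOR_CONCEPTS = (
    ("ICD-9", "35.01", "CLOSED HEART VALVOTOMY AORTIC VALVE"),
    ("ICD-9", "35.02", "CLOSED HEART VALVOTOMY MITRAL VALVE"),
    ("ICD-9", "35.11", "OPEN HEART VALVULOPLASTY AORTIC VALVE"),
    ("ICD-9", "35.21", "REPLACEMENT OF AORTIC VALVE WITH TISSUE GRAFT"),
    ("ICD-9", "36.10", "AORTOCORONARY BYPASS UNSPECIFIED"),
    ("ICD-9", "36.11", "AORTOCORONARY BYPASS OF ONE CORONARY ARTERY"),
    ("ICD-9", "36.12", "AORTOCORONARY BYPASS OF TWO CORONARY ARTERIES"),
)

_OUTCOME_CONCEPTS = (
    ("ICD-9", "584.5", "ACUTE KIDNEY FAILURE WITH TUBULAR NECROSIS"),
    ("ICD-9", "584.9", "ACUTE KIDNEY FAILURE UNSPECIFIED"),
)


def default_heart_surgery_config(n_patients: int, seed: int) -> SynthConfig:
    """The shipped study conditions: an enriched warehouse where 25% of
    patients undergo heart surgery (anchor), 8.3% of those develop acute
    kidney injury within 28 days (3% within 7), and pre-anchor creatinine
    runs 0.5 mg/dL higher in future-AKI patients — the planted predictive
    signal."""
    if n_patients < 100:
        raise ConfigError("default study config needs n_patients >= 100")
    labs = tuple(
        NumericConcept(code, desc, prev, mean, sd, bsd, unit)
        for code, desc, prev, mean, sd, bsd, unit in _LAB_PANEL
    )
    vitals = tuple(
        NumericConcept(code, desc, prev, mean, sd, bsd, unit,
                       context="VITALS", dimension="procedure")
        for code, desc, prev, mean, sd, bsd, unit in _VITALS
    )
    concepts = tuple(
        [CodedConcept("diagnosis", "ICD-9", code, desc, prev)
         for code, desc, prev in _DIAGNOSES]
        + [CodedConcept("material", "DRUG", code, desc, prev)
           for code, desc, prev in _DRUGS]
        + [CodedConcept("procedure", "ICD-9", code, desc, prev)
           for code, desc, prev in _EXTRA_PROCEDURES]
    )
    return SynthConfig(
        seed=seed,
        n_patients=n_patients,
        concepts=concepts,
        labs=labs,
        vitals=vitals,
        anchor_concepts=_ANCHOR_CONCEPTS,
        anchor_prevalence=0.25,
        anchor_min_age_years=18.0,
        outcome_concepts=_OUTCOME_CONCEPTS,
        p_onset_7d=0.03,
        p_onset_8_28d=0.053,
        p_background_outcome=0.02,
        signal_lab_code="CREA",
        signal_shift=0.5,
    )


def null_signal_config(n_patients: int, seed: int) -> SynthConfig:
    """Same study conditions with the planted creatinine signal removed;
    a null model against which discrimination should collapse to chance."""
    return replace(default_heart_surgery_config(n_patients, seed), signal_shift=0.0)
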