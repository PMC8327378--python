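# Methods

This note records the model of the data, the semantics the package
fixes where the field's informal vocabulary is ambiguous, the synthetic
generator's assumptions, and the numerical conventions that change
outputs. Everything stated here is exercised by the test suite or the
acceptance script; nothing is an unverified claim.

## Data model

The warehouse is a simplified i2b2-style star schema: a narrow `fact`
table (one row per atomic observation) surrounded by dimension tables
for patients, encounters and concepts, with a `group_map` table between
facts and concepts. Facts reference *group keys*; a group maps to one or
more concepts of a single dimension, and singleton groups wrap lone
concepts, so there is exactly one join path
(`fact → group_map → dimension`) for procedures, diagnoses and
materials. Metadata concepts (where laboratory tests live) are linked
directly by `metadata_key`. This is the smallest schema that still
exercises the fact→group→dimension join structure that makes star-schema
queries expensive and error-prone in practice.

Timestamps are integer **days of patient age**, the convention of a
deidentified warehouse in which every patient has a private day-offset
timeline; `birth_offset_days` is kept explicit (always 0) so the
convention is testable. All windows and ages are day-granular.
Descriptions are stored uppercase and matched case-insensitively as
substrings; codes are matched case-sensitively, with `%` as a
multi-character wildcard (no wildcard means exact equality).

## Condition semantics

Ten condition classes map onto the schema as follows: `Diagnosis` →
diagnosis dimension; `Procedure`, `Measurement`, `VitalSign` → procedure
dimension, where `Measurement` additionally requires a numeric value and
`VitalSign` defaults to the `VITALS` context — so the subset relations
VitalSign ⊆ Measurement ⊆ Procedure hold by construction; `Material`,
`Drug` → material dimension (`Drug` defaults to the `DRUG` context);
`LabValue` → metadata dimension with a numeric value; `Metadata` →
metadata dimension; `Encounter` matches encounter rows themselves
(timestamped at `begin_day`); `Patient` matches patient attributes.
`Encounter`, `Metadata` and `Patient` cannot be initialized from codes.

Three semantic choices are fixed and deliberate:

- **AND is patient-level.** `A & B` admits the patients satisfying both
  operands. When all operands are of one condition class, the surviving
  fact rows are the left operand's (restricted to admitted patients);
  across classes they are the union of all operands' rows. Fact-level or
  same-encounter conjunction is out of scope, as is NOT — exclusion
  criteria are not expressible and must be handled downstream (see the
  demo's `exclude_prior_outcome` flag for the one case the pipeline
  needs).
- **Patient conditions carry no facts.** `Patient(gender="male")`
  constrains the patient set; its fact set is empty. A cohort admitted
  purely by patient attributes therefore has no index event and is
  anchored at day 0 (birth).
- **Age filters apply at the time of the matching fact**, not at query
  time, with inclusive bounds and 365.25 days per year. Because days are
  integers, bounds are resolved at whole-day granularity: a fact is
  retained when its day is within half a day of the bound
  (`time_day ≥ min_age·365.25 − 0.5`), so the fact on a patient's
  6,574th day — their 18th birthday at day resolution — passes
  `min_age=18`.

Conditions serialize to a versioned JSON document (`{"version": "1",
"root": …}`) with stable key order; deserialization of an unknown class
or version fails loudly rather than guessing.

## Cohorts, anchors and onset

A cohort is the set of patients with at least one matching occurrence.
The **anchor is the earliest matching fact** — the standard index-event
convention; the alternative (latest, or all events) would change every
downstream window and is intentionally not configurable. **Onset is
strictly after the anchor day**: an outcome coded on the surgery day
itself is treated as pre-existing rather than post-operative, which
avoids labeling conditions documented during the index admission as
outcomes. Windows everywhere are closed intervals of relative days;
`[-180, 0]` includes the anchor day. `has_onset` with window w₁ ≤ w₂ is
pointwise monotone, and `occurs` is monotone under window nesting; both
properties are tested.

## Feature pivoting

Coverage counts **distinct patients** (not facts): the fraction of
cohort members with ≥ 1 in-window fact for the feature. Features at
exactly the threshold are kept (≥). Feature identity is
`(context, code)` when the concept is coded, otherwise the uppercased
description — distinct codes never merge on a shared display name.
Value-less classes are encoded as occurrence features (`any` ∈ {0,1},
`count` ∈ ℕ), the standard phenotyping convention; requesting `mean` or
`median` for them is a configuration error. The median of an
even-length list is the mean of the middle two values; user-supplied
reducers receive the patient's in-window values sorted by fact time. A
cell is null **iff** the patient has zero in-window facts for that
feature; no imputation is performed — sparse-feature handling beyond
the coverage threshold belongs to the modeling layer.

## SAX

`sax(series, n_segments, α)` is z-normalize → PAA → quantile binning.
The standard deviation uses denominator n; a constant series normalizes
to all zeros (guarded division). PAA with a length not divisible by the
segment count uses fractional frames: each point contributes to the
segment(s) covering its index interval in proportion to overlap.
Breakpoints are the standard-normal quantiles at 1/α … (α−1)/α
(symmetric about 0 to 1e-9); a segment mean exactly equal to a
breakpoint maps to the **higher** symbol, so a constant series with
α = 2 reads `bb…b`. The word is invariant under affine transforms of the
input. Irregular sampling is handled by taking values in time order and
ignoring gaps — no interpolation; callers who need calendar-spaced
words should resample first. Equiprobability of the α symbols holds
when the normalized segment values are standard normal, i.e. with one
point per segment on i.i.d. Gaussian input; averaging k points per
segment shrinks segment means by √k and concentrates the word in the
middle symbols, which is expected behavior, not an error. SAX distances
(MINDIST), numerosity reduction and motif discovery are out of scope.

## Synthetic generator

The generator emulates the *shape* of a deidentified warehouse, not
clinical reality: its purpose is to make every query-path component
checkable against planted truth.

Per patient, in a fixed documented draw order from one seeded
`numpy.random.Generator` (gender, race, deceased flag, age at first
encounter, anchor, outcome, encounter days, coded events, lab offsets,
per-encounter panels): demographics; an observation span of
`followup_days` (default 730) starting at an age drawn from N(60, 15)
years; encounters as a base process (4/year) plus a burst (×4 within
±30 days) around the anchor — reproducing the empirical phenomenon that
visit density peaks around an index surgery; an anchor event (heart
surgery, ICD-9-like codes under `35.`/`36.1`) with probability 0.25,
placed only where the patient is ≥ 18 years old; an outcome (AKI,
`584.x`) strictly after the anchor with P = 0.03 within 7 days and
P = 0.053 in days 8–28, so the 28-day outcome fraction among surgery
patients is 0.083; background outcomes (P = 0.02) only in non-anchor
patients, so planted labels stay identifiable; a ~30-test lab panel and
six vital signs with per-test sampling prevalences, each value Gaussian
around a patient-shifted mean (i.i.d. within patient — no
autocorrelation, which suffices to test windows and aggregations; SAX
behavior is tested on separately constructed series); and occasional
multi-concept groups (P = 0.15 when ≥ 2 same-dimension coded events
share an encounter) so group-join expansion is exercised.

The defaults are deliberate: the anchor prevalence (25 %) makes the
warehouse *enriched* relative to any real population so that cohorts are
well-populated at desk scale; the 28-day outcome fraction (8.3 %) and
the cohort's ~60/40 male/female split and ~61-year mean age mirror the
magnitudes reported for real post-cardiac-surgery AKI cohorts; the
planted signal — pre-operative creatinine shifted +0.5 mg/dL (2 within-
draw SDs) in future-AKI patients — is strong by design, because its job
is to verify that the extraction pipeline *transmits* a signal, not to
pose a hard learning problem. What the generator does **not** emulate:
coding noise and miscoding, care-pattern confounding, informative
missingness, inter-lab correlation, free text, and real ontology depth.
Passing tests therefore demonstrate correctness of the query/label/pivot
machinery on warehouse-shaped data, not model performance on real EHRs.

Ground truth records every planted coded event and numeric draw;
labels in the truth document are re-derived from the event list with the
same strict-after/closed-window definitions, and the invariant tested is
that the full pipeline (condition → cohort → `has_onset`) reproduces
them with zero discrepancies. Same seed ⇒ byte-identical ground-truth
JSON and row-identical tables.

## The prediction demo

The end-to-end demo is an integration smoke test of the extraction
stack, not a modeling contribution: pre-operative features (labs and
vitals over `[-180, 0]` with a 0.5 coverage threshold; diagnoses over
`[-1825, -1]`; age and gender) feed a median-imputed, standardized
logistic regression under stratified 5-fold cross-validation. With the
planted signal the 28-day AUC is well above chance (≈ 0.85 at
n = 5,000); with the signal removed it sits at chance level. The
`exclude_prior_outcome` flag (default off) drops members with an outcome
fact on or before the anchor day — both behaviors are legitimate study
designs, and the default keeps the cohort definition purely
condition-based.

## Problem sizes and storage

The validation workloads were sized to run comfortably on a single CPU:
brute-force cross-checks (query-path vs reference evaluator, pivot vs
reference pivot) use warehouses of ≤ 10,000 facts (100 patients, 1-year
follow-up); planted-truth recovery and generator calibration run at
n = 12,000 patients (~1.4 M facts); the prediction demo at n = 5,000.
The reference evaluator is plain Python over a full table dump and
deliberately shares no code with the SQL path.

Storage is SQLite through the standard library's `sqlite3`; table and
column names are part of the public contract. Any workload here is far
below the scale where a columnar engine would matter, and keeping the
dependency surface to the standard library makes the artifact fully
reproducible offline.

## Known limitations

- No NOT/exclusion operator; no same-encounter or same-fact conjunction.
- No ontology integration (LOINC/SNOMED); codes are opaque strings with
  prefix-wildcard semantics only.
- Anchor multiplicity is resolved to the earliest event only.
- `values_for` and the pivot ignore `text_value`; only numeric values
  are aggregated.
- The generator's lab values are i.i.d. within patient; longitudinal
  autocorrelation, trends before outcomes, and unit heterogeneity are
  not modeled.
- Privacy/anonymization of real data is out of scope; the synthetic
  warehouse is already deidentified by construction.
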