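# starcohort

Cohort building, outcome labeling and feature extraction over
**star-schema clinical data warehouses**, plus a seeded synthetic
warehouse generator that makes the whole stack testable offline.

## The problem

Clinical prediction studies start long before any model is fit: a
researcher must translate inclusion criteria into SQL against a data
warehouse whose atomic *facts* (one row per diagnosis code, lab result,
medication, vital sign) live in a narrow fact table and only become
meaningful after joins through grouping and dimension tables. The result
must then be reshaped into one row per patient, aligned in time to an
index event, with outcomes labeled and sparse features pruned. This
package provides that pipeline as a composable Python API for an
i2b2-style star schema:

- **Conditions** — typed leaves (`Diagnosis`, `Procedure`, `Measurement`,
  `VitalSign`, `Material`, `Drug`, `Encounter`, `Metadata`, `LabValue`,
  `Patient`) built from clinical codes (`%` is a wildcard:
  `Diagnosis(code="584.%", context="ICD-9")` selects the whole ICD-9 584
  family), from description substrings, or from patient attributes;
  combined with `&`/`|` at any nesting depth, optionally restricted by
  age at the time of the fact. Conditions serialize to JSON so cohort
  definitions can be shared and re-run.
- **Cohorts** — the set of patients with ≥ 1 matching occurrence, each
  *anchored* at the earliest matching fact. `has_onset(cohort, name,
  condition, window_days)` labels members 1 when the condition occurs
  strictly after the anchor and within the window; `occurs` and
  `values_for` count and extract facts in closed windows of days relative
  to the anchor.
- **Features** — `get_pivoted_features(cohort, config, db)` turns
  in-window facts into a wide patient × feature matrix: per condition
  class you give a time window, a *coverage threshold* (the minimum
  fraction of patients that must have the feature) and aggregation
  functions (`min`, `max`, `mean`, `median`, `count`, `any`, or your own
  reducer). Cells are null exactly when a patient has no in-window fact.
- **Time series** — `z_normalize`, piecewise aggregate approximation
  (`paa`) and SAX symbolization (`sax`) for longitudinal values.
- **Exploration** — encounter-timeline occupancy matrices,
  feature-count-versus-threshold curves, demographic tables (tabular
  first; matplotlib rendering optional).
- **Synthetic data** — `generate(config, path)` writes a full SQLite
  warehouse plus a `GroundTruth` document recording every planted event,
  so cohort membership, anchors and onset labels can be checked with
  zero tolerance. The shipped configuration emulates a heart-surgery →
  acute-kidney-injury study: anchors are ICD-9 procedure codes under
  `35.`/`36.1`, outcomes are `584.x` diagnoses (8.3 % of surgery patients
  within 28 days), and pre-operative creatinine runs higher in future-AKI
  patients — a planted, recoverable predictive signal.

## Worked example

```python
from starcohort import (build_cohort, default_heart_surgery_config,
                        demographics, generate, has_onset)
from starcohort.conditions import Diagnosis, Procedure

db, truth = generate(default_heart_surgery_config(2000, seed=1), "warehouse.sqlite")

heart_surgery = (Procedure(code="35.%", context="ICD-9").age(min_age=18)
                 | Procedure(code="36.1%", context="ICD-9").age(min_age=18))
cohort = build_cohort(heart_surgery, db)
print(len(cohort))                      # 483  (== planted surgery patients)
print(demographics(cohort))             # 293 male / 190 female, mean age ~61 y

aki = Diagnosis(code="584.%", context="ICD-9")
labels = has_onset(cohort, "aki", aki, window_days=28)
print(sum(labels.labels.values()))      # 40 onsets, identical to ground truth
```

Running `examples/06_aki_prediction.py` (the full pipeline through a
cross-validated logistic regression at n = 2,000) prints:

```
planted signal: 28-day AUC 0.780, AUPRC 0.369 (40 positives / 483 patients)
   null signal: 28-day AUC 0.487, AUPRC 0.104 (40 positives / 483 patients)
```

i.e. the planted pre-operative creatinine shift is recovered as
discrimination well above chance, and removing it collapses the AUC to
~0.5 — the pipeline measures the planted signal and nothing else. Each
script in `examples/` demonstrates one capability and explains the
numbers it prints.

A thin CLI wraps the same library surface:

```bash
starcohort init-config --n-patients 5000 --seed 1 -o cfg.json
starcohort generate --config cfg.json --out wh.sqlite
starcohort cohort --db wh.sqlite --condition heart.json --out-prefix hs
starcohort features --db wh.sqlite --cohort-prefix hs --pivot-config pivot.json --out feat.csv
starcohort demo-aki --out-dir demo/ --n-patients 5000 --seed 1
```

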