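"""Cohort exploration tables: encounter timeline and threshold curves.

The encounter-timeline matrix shows, for day windows around the surgery,
what fraction of patients had how many encounters; the threshold curve
shows how many features survive as the coverage bar rises.
"""

import tempfile, os

from starcohort import build_cohort, default_heart_surgery_config, generate
from starcohort.conditions import Procedure
from starcohort.explore import encounter_timeline, feature_counts_by_threshold

workdir = tempfile.mkdtemp()
db, _ = generate(default_heart_surgery_config(2000, seed=1),
                 os.path.join(workdir, "warehouse.sqlite"))
cohort = build_cohort(
    Procedure(code="35.%", context="ICD-9").age(min_age=18)
    | Procedure(code="36.1%", context="ICD-9").age(min_age=18), db
)

timeline = encounter_timeline(cohort)
print("encounter timeline (fraction of patients per count bin):")
print(timeline.round(2).to_string())

curve = feature_counts_by_threshold(
    cohort, ["LabValue", "Diagnosis"], (-180, 0), [0.0, 0.25, 0.5, 0.75, 1.0], db
)
print("\nfeatures surviving each coverage threshold:")
print(curve.pivot(index="threshold", columns="condition_class",
                  values="n_features").to_string())
# Encounter occupancy peaks in the windows containing the surgery (the
# generator plants a visit burst around the anchor), and feature counts
# fall monotonically as the threshold rises.
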