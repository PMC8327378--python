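"""Extract a modeling-ready feature matrix with `get_pivoted_features`.

Pre-operative labs over the 180 days up to surgery, kept only when at
least half the cohort has the test, aggregated as min/median/max.
"""

import tempfile, os

from starcohort import (
    PivotConfig, build_cohort, default_heart_surgery_config, generate,
    get_pivoted_features,
)
from starcohort.conditions import Procedure

workdir = tempfile.mkdtemp()
db, _ = generate(default_heart_surgery_config(2000, seed=1),
                 os.path.join(workdir, "warehouse.sqlite"))
cohort = build_cohort(
    Procedure(code="35.%", context="ICD-9").age(min_age=18)
    | Procedure(code="36.1%", context="ICD-9").age(min_age=18), db
)

pivot_config = PivotConfig({
    "LabValue": {"timewindow": [-180, 0], "threshold": 0.5,
                 "aggfuncs": ["min", "median", "max"]},
})
matrix = get_pivoted_features(cohort, pivot_config, db)

print(f"matrix: {matrix.shape[0]} patients x {matrix.shape[1]} columns")
print("first columns:", list(matrix.columns[:3]))
one = matrix.iloc[0]
print(f"example patient creatinine (mg/dL): "
      f"min={one['LabValue__LAB:CREA__min']:.2f} "
      f"median={one['LabValue__LAB:CREA__median']:.2f} "
      f"max={one['LabValue__LAB:CREA__max']:.2f}")
# One row per cohort member; a null cell means the patient had no
# in-window result for that test (sparse labs below the 50% coverage
# threshold are dropped entirely).
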