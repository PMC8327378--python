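"""End-to-end: predict post-surgical AKI from pre-operative features.

Runs the whole pipeline (generate -> cohort -> labels -> features ->
cross-validated logistic regression) twice: once with the generator's
planted creatinine signal and once with it removed.
"""

import tempfile

from starcohort.demo import run_aki_demo

workdir = tempfile.mkdtemp()
planted = run_aki_demo(f"{workdir}/planted", n_patients=2000, seed=1)
null = run_aki_demo(f"{workdir}/null", n_patients=2000, seed=1, null_signal=True)

for name, report in (("planted signal", planted), ("null signal", null)):
    m = report["windows"]["28"]
    print(f"{name:>14}: 28-day AUC {m['auc']:.3f}, AUPRC {m['auprc']:.3f} "
          f"({m['n_positive']} positives / {report['cohort_size']} patients)")
# The planted pre-operative creatinine shift makes future-AKI patients
# separable (AUC well above chance); removing it collapses AUC to ~0.5,
# confirming the pipeline measures the planted signal and nothing else.
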