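"""Simulate the synthetic Go/NoGo cohort.

Generates 55 subjects (15 low / 25 middle / 15 high trauma analogs) with
300-trial sessions, phase-coupled 20-node source signals whose coupling
weakens with trauma load, group-graded psychological covariates, and a
projection to 32 synthetic sensors.  Writes the cohort table under
results/pipeline/ and the epoch tensors under scratch/pipeline/.
"""

import pandas as pd

from _paths import RUN_DIR, SCRATCH_DIR
from plvnet.experiments import study_config
from plvnet.pipeline import PipelineRun

run = PipelineRun(study_config(seed=0), RUN_DIR, scratch_dir=SCRATCH_DIR)
run.simulate()

cohort = pd.read_csv(RUN_DIR / "cohort.csv")
print(f"simulated {len(cohort)} subjects -> {RUN_DIR / 'cohort.csv'}")
print("\nquartile groups (CTQ total, mean +/- SD):")
for g, sub in cohort.groupby("group_label"):
    print(f"  {g:>6}: n={len(sub):2d}  CTQ {sub.ctq_total.mean():5.1f} +/- "
          f"{sub.ctq_total.std(ddof=1):4.1f}  SAI {sub.sai.mean():4.1f}  "
          f"BDI {sub.bdi.mean():4.1f}  sigma {sub.sigma.mean():.3f}")
print("\nhigher trauma load -> higher anxiety/depression scores and larger "
      "phase jitter (weaker coupling), as designed.")
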