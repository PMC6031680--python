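"""Minimum-norm source estimation.

Maps the 32-channel sensor epochs back to the 20 cortical nodes through
the regularized minimum-norm inverse of the synthetic lead field
(lambda set from an assumed SNR of 3).
"""

import json

from _paths import RUN_DIR, SCRATCH_DIR
from plvnet.experiments import study_config
from plvnet.pipeline import PipelineRun

run = PipelineRun(study_config(seed=0), RUN_DIR, scratch_dir=SCRATCH_DIR)
run.localize()

manifest = json.loads((RUN_DIR / "manifest.json").read_text())
stage = manifest["stages"]["localize"]
print(f"localized node time series -> {SCRATCH_DIR / 'source'}")
print(f"  sensors: {stage['n_sensors']}, lambda = {stage['lambda']:.4f} "
      f"(SNR {stage['snr']})")
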