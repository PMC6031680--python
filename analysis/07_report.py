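"""Render the run report: group mean +/- SD tables per index and band,
post-hoc p-values, effect sizes, and the correlation summary."""

from _paths import RUN_DIR, SCRATCH_DIR
from plvnet.experiments import study_config
from plvnet.pipeline import PipelineRun

run = PipelineRun(study_config(seed=0), RUN_DIR, scratch_dir=SCRATCH_DIR)
text = run.render_report()
print(f"wrote {RUN_DIR / 'report.md'} ({len(text.splitlines())} lines)")
print("\n".join(text.splitlines()[:28]))
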