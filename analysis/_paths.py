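"""Shared locations for the analysis drivers (run them from anywhere)."""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "results" / "pipeline"
SCRATCH_DIR = ROOT / "scratch" / "pipeline"
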