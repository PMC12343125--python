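"""Shared configuration for the numbered analysis drivers.

All drivers write under results/analysis/ and draw their settings from one
place so the stages compose into a single reproducible study.
"""

from pathlib import Path

from fbdstrata.compare import default_synthetic_config

SEED = 20250929
RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def study_config() -> dict:
    cfg = default_synthetic_config()
    cfg["figures"] = True
    return cfg
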