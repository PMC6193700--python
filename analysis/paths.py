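"""Shared locations for the analysis scripts (all relative to the repo root)."""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATA = RESULTS / "data"
SEED = 20240901  # one seed for the whole analysis chain
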