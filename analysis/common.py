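"""Shared paths and settings for the numbered analysis drivers."""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
DATA = RESULTS / "01_data"
SEED = 1
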