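"""Shared output locations for the analysis drivers.

Small summary tables land in results/; bulky intermediates (full cohort
tables, z-scores, NIfTI phantoms) land in scratch/ and are regenerated by
re-running the numbered scripts in order.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "analysis"

RESULTS.mkdir(parents=True, exist_ok=True)
SCRATCH.mkdir(parents=True, exist_ok=True)
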