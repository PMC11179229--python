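"""Shared locations for the analysis drivers.

Bulky intermediates (genotype matrices, plot-level tables, full scan output)
live under scratch/; compact result tables go to results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"
SEED = 1

SCRATCH.mkdir(parents=True, exist_ok=True)
RESULTS.mkdir(parents=True, exist_ok=True)
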