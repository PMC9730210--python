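"""Shared settings for the analysis drivers.

One simulated cohort stands in for the pooled clinical sample: the
"paper-like" scenario (three staging groups of 100 persons, 6 days x 10
prompts) with seed 42. Every driver regenerates it deterministically, so
no intermediate data files need to be committed; the full prompt-level
CSV lands under scratch/ for inspection.
"""

from pathlib import Path

from esmstress.simulate import get_scenario

SEED = 42
CONFIG = get_scenario("paper-like")
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def cohort():
    from esmstress import generate
    return generate(CONFIG, seed=SEED)
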