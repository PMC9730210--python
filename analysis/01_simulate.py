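"""Generate the synthetic ESM cohort and record its ground truth.

Writes the planted effect structure to results/ground_truth.yaml and the
full prompt-level CSV to scratch/ (it is regenerated deterministically
by every later step, so it is not a pipeline dependency).
"""

import sys
from pathlib import Path

import yaml

sys.path.insert(0, str(Path(__file__).parent))
from importlib import import_module

cfg_mod = import_module("00_config")

from esmstress import write_esm_long


def main() -> None:
    ds, truth = cfg_mod.cohort()
    cfg_mod.RESULTS.mkdir(exist_ok=True)
    cfg_mod.SCRATCH.mkdir(exist_ok=True)

    with open(cfg_mod.RESULTS / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(truth.as_dict(), fh, sort_keys=True)
    write_esm_long(ds, cfg_mod.SCRATCH / "cohort.csv")

    answered = ds.answered()
    print(f"cohort: {ds.n_persons} persons, {ds.n_prompts} scheduled prompts, "
          f"{len(answered)} answered ({100 * len(answered) / ds.n_prompts:.0f}%)")
    print(f"planted baseline offsets: {truth.baseline_offset}")
    print(f"planted reactivity:       {truth.reactivity}")
    print(f"planted recovery deficits:{truth.recovery_deficit}")
    print(f"ground truth -> {cfg_mod.RESULTS / 'ground_truth.yaml'}")


if __name__ == "__main__":
    main()
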