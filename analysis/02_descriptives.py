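"""Compliance filtering and sample descriptives.

Applies the two-stage compliance rule (prompts answered within 15
minutes; persons with at least 20 compliant prompts), scores affect and
stress, and writes the per-group descriptive table with between-group
tests — the analog of a cohort characteristics table.
"""

import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
cfg_mod = import_module("00_config")

from esmstress import (
    apply_compliance_filter,
    compliance_percentage,
    derive_prompts,
    descriptive_table,
)
from esmstress.data import exclusion_log_frame


def main() -> None:
    ds, _ = cfg_mod.cohort()
    filtered, logs = apply_compliance_filter(ds)
    derived = derive_prompts(filtered)
    cfg_mod.RESULTS.mkdir(exist_ok=True)

    exclusion_log_frame(logs).to_csv(cfg_mod.RESULTS / "exclusion_log.csv", index=False)
    res = descriptive_table(filtered, derived)
    res["table"].to_csv(cfg_mod.RESULTS / "table1_descriptives.csv", index=False)
    res["tests"].to_csv(cfg_mod.RESULTS / "table1_tests.csv", index=False)

    scheduled = cfg_mod.CONFIG.days * cfg_mod.CONFIG.beeps_per_day
    print(f"analytic sample: {filtered.n_persons} persons, "
          f"{filtered.n_prompts} compliant prompts")
    for g, n in res["group_n"].items():
        answered = filtered.answered()
        per = answered[answered["group"] == g].groupby("person_id").size().mean()
        pct = compliance_percentage(int(round(per)), scheduled)
        print(f"  {g}: n={n}, mean compliance {pct}% ({per:.0f}/{scheduled} prompts)")
    sig = res["tests"][res["tests"]["p"] < 0.05]["characteristic"].tolist()
    print(f"between-group differences at alpha=.05: {sig or 'none'}")


if __name__ == "__main__":
    main()
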