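import io

import numpy as np
import pandas as pd
import pytest

from esmstress import ESMDataset, SimConfig, generate, read_esm_long

HEADER = (
    "person_id,group,age,gender,day_index,beep_index,scheduled_time,"
    "response_delay_min,pa_cheerful,pa_relaxed,pa_satisfied,"
    "event_pleasantness,act_energy,act_skilled,act_challenge,act_prefer_else"
)


def make_csv(rows: list[str]) -> io.StringIO:
    return io.StringIO(HEADER + "\n" + "\n".join(rows) + "\n")


def prompt_row(pid="p1", group="control", age=30, gender="female", day=1, beep=1,
               time="08:00", delay=5, pa=(4, 4, 4), ev=0, act=(4, 4, 4, 4)) -> str:
    def s(v):
        return "" if v is None else str(v)
    return ",".join(
        [pid, group, s(age), gender, str(day), str(beep), time, s(delay)]
        + [s(v) for v in pa] + [s(ev)] + [s(v) for v in act]
    )


@pytest.fixture(scope="session")
def tiny_dataset() -> ESMDataset:
    """3 persons x 2 days x 3 beeps, fully answered, hand-built."""
    rows = []
    for i, (g, age, gender) in enumerate(
        [("control", 30, "female"), ("at_risk", 40, "male"), ("patient", 50, "female")]
    ):
        for d in (1, 2):
            for b in (1, 2, 3):
                rows.append(prompt_row(
                    pid=f"p{i}", group=g, age=age, gender=gender, day=d, beep=b,
                    time=f"{7 + b}:00", delay=3, pa=(3 + i, 4, 4),
                    ev=1 if b != 2 else -2, act=(2, 6, 2, 2) if b != 2 else (6, 2, 6, 6),
                ))
    return read_esm_long(make_csv(rows))


def small_config(n=12, **overrides) -> SimConfig:
    base = dict(n_per_group={g: n for g in ("control", "at_risk", "patient")})
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset (+truth) reused across read-only tests."""
    return generate(small_config(12), seed=7)
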