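"""Time-since-stressor coding of affect trajectories.

For each person-day and stress type, the first answered prompt flagged as
stressful becomes t0 (reactivity); the answered prompt immediately before
it becomes the baseline t−1; the following answered prompts become
t1..tK. Days without a stressor, days whose first answered prompt is
already stressful (no baseline available), and persons who never report
the stress type are excluded, as are prompts before t−1 and beyond tK.
Labels are indexed over answered prompts (measurement occasions), so a
missed beep shifts labels to the next answered prompt.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd

STRESS_TYPES = ("event", "activity", "composite")

#: default follow-up window length per stress type (prompts after t0)
DEFAULT_MAX_LAG = {"event": 1, "activity": 2, "composite": 2}


def _flag_column(stress_type: str) -> str:
    if stress_type not in STRESS_TYPES:
        raise ValueError(f"unknown stress type {stress_type!r}; use one of {STRESS_TYPES}")
    return f"{stress_type}_stress"


def find_first_stressor(day_prompts: pd.DataFrame, stress_type: str):
    """Smallest beep_index of ``day_prompts`` whose stress flag is true.

    ``day_prompts`` must be one person-day of answered prompts sorted by
    beep_index. Returns None on a stress-free day.
    """
    col = _flag_column(stress_type)
    hits = day_prompts.loc[day_prompts[col].astype(bool), "beep_index"]
    if hits.empty:
        return None
    return int(hits.iloc[0])


@dataclass
class ExclusionSummary:
    """Exclusion accounting for one stress type, brute-force checkable."""

    stress_type: str
    n_persons_never_stressed: int = 0
    n_days_without_stress: int = 0
    n_days_first_prompt_stressor: int = 0
    n_prompts_pre_baseline: int = 0
    n_prompts_beyond_window: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, int) and v < 0:
                raise ValueError("exclusion counts must be nonnegative")


def code_time_since(
    derived: pd.DataFrame, stress_type: str, max_lag: int | None = None
) -> pd.DataFrame:
    """Label every answered prompt with its position relative to the day's
    first stressor of ``stress_type``.

    Returns ``derived`` plus columns ``time_since`` ('t-1', 't0', 't1', ...
    or None), ``included`` (bool) and ``exclusion_reason``. ``max_lag`` is
    the number of follow-up prompts modeled after t0 (defaults per stress
    type: event 1, activity/composite 2).
    """
    if max_lag is None:
        max_lag = DEFAULT_MAX_LAG[stress_type]
    if max_lag < 1:
        raise ValueError("max_lag must be at least 1")
    col = _flag_column(stress_type)

    out = derived.sort_values(["person_id", "day_index", "beep_index"]).copy()
    flag = out[col].astype(bool)
    by_person = out.groupby("person_id")[col]
    by_day = out.groupby(["person_id", "day_index"])

    ever = by_person.transform("any").astype(bool)
    day_has = by_day[col].transform("any").astype(bool)
    pos = by_day.cumcount()
    first_pos = pos.where(flag).groupby(
        [out["person_id"], out["day_index"]]
    ).transform("min")
    k = pos - first_pos  # prompt lag relative to the day's first stressor

    reason = pd.Series(None, index=out.index, dtype=object)
    reason[~ever] = "never_stressed"
    reason[ever & ~day_has] = "no_stress_day"
    usable = ever & day_has
    reason[usable & (first_pos == 0)] = "first_prompt_stressor"
    coded = usable & (first_pos > 0)
    reason[coded & (k < -1)] = "pre_baseline"
    reason[coded & (k > max_lag)] = "beyond_window"

    in_window = coded & (k >= -1) & (k <= max_lag)
    labels = pd.Series(None, index=out.index, dtype=object)
    labels[in_window] = "t" + k[in_window].astype(int).astype(str)
    labels[in_window & (k == -1)] = "t-1"

    out["time_since"] = labels.where(labels.notna(), None)
    out["included"] = in_window
    out["exclusion_reason"] = reason.where(reason.notna(), None)
    out["stress_type"] = stress_type
    return out


def flag_subsequent_stress(frame: pd.DataFrame, derived: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mark the presence of the same stress type at follow-up prompts.

    For rows labeled t1..tK the indicator is that row's own stress flag;
    at t−1 and t0 it is undefined (left missing) and never enters the
    covariate column. ``derived`` is accepted for interface symmetry when
    ``frame`` already carries the stress flags (the usual case).
    """
    out = frame.copy()
    col = _flag_column(out["stress_type"].iloc[0])
    src = out if derived is None else out.merge(
        derived[["person_id", "day_index", "beep_index", col]],
        on=["person_id", "day_index", "beep_index"], how="left", suffixes=("", "_src"),
    )
    flags = src[col] if derived is None else src[f"{col}_src"].fillna(src[col])
    is_followup = out["time_since"].astype(str).str.fullmatch(r"t[1-9]\d*")
    out["subsequent_stress"] = pd.array(
        [bool(f) if fu else None for f, fu in zip(flags, is_followup)],
        dtype="boolean",
    )
    return out


def exclusion_summary(frame: pd.DataFrame) -> ExclusionSummary:
    """Tally the exclusions recorded by :func:`code_time_since`."""
    st = frame["stress_type"].iloc[0]
    reason = frame["exclusion_reason"]
    never = frame.loc[reason == "never_stressed", "person_id"].nunique()
    no_stress = (
        frame.loc[reason == "no_stress_day", ["person_id", "day_index"]]
        .drop_duplicates().shape[0]
    )
    first = (
        frame.loc[reason == "first_prompt_stressor", ["person_id", "day_index"]]
        .drop_duplicates().shape[0]
    )
    return ExclusionSummary(
        stress_type=st,
        n_persons_never_stressed=int(never),
        n_days_without_stress=int(no_stress),
        n_days_first_prompt_stressor=int(first),
        n_prompts_pre_baseline=int((reason == "pre_baseline").sum()),
        n_prompts_beyond_window=int((reason == "beyond_window").sum()),
    )
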