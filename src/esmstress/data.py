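"""Data model, long-format I/O, compliance filtering and descriptives for
prompt-level experience-sampling datasets.

The on-disk format is a long CSV with one row per *scheduled* prompt.
Unanswered prompts are rows whose ``response_delay_min`` is empty; item
responses may be empty (missing) independently. Person-level covariates
(group, age, gender) are repeated on every row of that person.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("patient", "at_risk", "control")

#: required columns of the long CSV, with (low, high) valid ranges for items
REQUIRED_COLUMNS = [
    "person_id", "group", "age", "gender", "day_index", "beep_index",
    "scheduled_time", "response_delay_min",
    "pa_cheerful", "pa_relaxed", "pa_satisfied",
    "event_pleasantness",
    "act_energy", "act_skilled", "act_challenge", "act_prefer_else",
]

ITEM_RANGES = {
    "pa_cheerful": (1, 7), "pa_relaxed": (1, 7), "pa_satisfied": (1, 7),
    "event_pleasantness": (-3, 3),
    "act_energy": (1, 7), "act_skilled": (1, 7),
    "act_challenge": (1, 7), "act_prefer_else": (1, 7),
}

PA_ITEMS = ["pa_cheerful", "pa_relaxed", "pa_satisfied"]
ACT_ITEMS = ["act_energy", "act_skilled", "act_challenge", "act_prefer_else"]
STRESS_ITEMS = ["event_pleasantness"] + ACT_ITEMS


class SchemaError(ValueError):
    """A mandatory column is absent or a person-level field is inconsistent."""


class IntegrityError(ValueError):
    """Duplicate (person, day, beep) keys or referential breakage."""


class NoAnalyzableDataError(RuntimeError):
    """All rows were removed by filtering; nothing left to analyze."""


@dataclass
class ExclusionLog:
    """Accounting record for one filtering stage."""

    stage: str
    reason: str
    n_prompts_removed: int
    n_persons_removed: int

    def __post_init__(self) -> None:
        if self.n_prompts_removed < 0 or self.n_persons_removed < 0:
            raise ValueError("exclusion counts must be nonnegative")


@dataclass
class ESMDataset:
    """A prompt-level ESM dataset: person table + prompt table + provenance.

    ``prompts`` holds one row per scheduled prompt (answered or not);
    ``persons`` one row per person with constant covariates. ``issues``
    records validation flags (out-of-range cells) without mutating data.
    """

    persons: pd.DataFrame
    prompts: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    issues: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["person_id", "day_index", "beep_index", "column", "value"]
        )
    )

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def n_prompts(self) -> int:
        return len(self.prompts)

    def answered(self) -> pd.DataFrame:
        """Prompts with a recorded response delay (i.e. answered)."""
        return self.prompts[self.prompts["response_delay_min"].notna()]

    def copy(self) -> "ESMDataset":
        return ESMDataset(
            self.persons.copy(), self.prompts.copy(),
            dict(self.provenance), self.issues.copy(),
        )


def _build_persons(prompts: pd.DataFrame) -> pd.DataFrame:
    per = prompts.groupby("person_id")[["group", "age", "gender"]].agg(
        lambda s: s.iloc[0]
    )
    # person-level fields must be constant across a person's rows
    nuniq = prompts.groupby("person_id")[["group", "age", "gender"]].nunique()
    bad = nuniq[(nuniq > 1).any(axis=1)]
    if len(bad):
        raise SchemaError(
            f"person-level fields vary within person(s): {list(bad.index[:5])}"
        )
    if (per["age"] <= 0).any():
        raise SchemaError("age must be positive for all persons")
    return per.reset_index()


def validate_ranges(prompts: pd.DataFrame) -> pd.DataFrame:
    """Flag out-of-range item values; rows are retained, nothing is coerced."""
    frames = []
    for col, (lo, hi) in ITEM_RANGES.items():
        vals = prompts[col]
        bad = vals.notna() & ((vals < lo) | (vals > hi))
        if bad.any():
            f = prompts.loc[bad, ["person_id", "day_index", "beep_index"]].copy()
            f["column"] = col
            f["value"] = vals[bad]
            frames.append(f)
    if frames:
        return pd.concat(frames, ignore_index=True)
    return pd.DataFrame(columns=["person_id", "day_index", "beep_index", "column", "value"])


def read_esm_long(path, schema: dict | None = None) -> ESMDataset:
    """Read a long-format prompt-level CSV into an :class:`ESMDataset`.

    Parameters
    ----------
    path : str or file-like
        CSV with one row per scheduled prompt.
    schema : dict, optional
        Mapping from the file's column names to the canonical names in
        :data:`REQUIRED_COLUMNS`, for files using different headers.

    Raises
    ------
    SchemaError
        If a mandatory column is missing (the error names it).
    IntegrityError
        If (person_id, day_index, beep_index) is duplicated.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    keys = ["person_id", "day_index", "beep_index"]
    dup = df.duplicated(subset=keys)
    if dup.any():
        raise IntegrityError(
            f"duplicate (person, day, beep) keys: "
            f"{df.loc[dup, keys].head().to_dict('records')}"
        )
    for col in ["day_index", "beep_index"]:
        df[col] = df[col].astype(int)
    for col in ["response_delay_min", "age"] + list(ITEM_RANGES):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    issues = validate_ranges(df)
    persons = _build_persons(df)
    prov = {
        "n_days": int(df["day_index"].max()),
        "n_beeps_per_day": int(df["beep_index"].max()),
        "source": str(path),
    }
    return ESMDataset(persons=persons, prompts=df, provenance=prov, issues=issues)


def write_esm_long(ds: ESMDataset, path) -> None:
    """Write the prompt table back to CSV with the canonical column order."""
    ds.prompts[REQUIRED_COLUMNS].to_csv(path, index=False)


def apply_compliance_filter(
    ds: ESMDataset, max_delay: float = 15.0, min_prompts: int = 20
) -> tuple[ESMDataset, list[ExclusionLog]]:
    """Apply the two-stage compliance rule.

    Stage 1 removes prompts that were unanswered, answered more than
    ``max_delay`` minutes after the signal, or answered with every
    positive-affect and stress item missing. Stage 2 then removes persons
    left with fewer than ``min_prompts`` prompts. Stages are logged
    separately so the accounting stays auditable.
    """
    prompts = ds.prompts
    delay = prompts["response_delay_min"]
    unanswered = delay.isna()
    late = delay > max_delay
    all_items_missing = (
        prompts[PA_ITEMS + STRESS_ITEMS].isna().all(axis=1) & ~unanswered
    )
    drop1 = unanswered | late | all_items_missing
    kept = prompts[~drop1]

    per_person = kept.groupby("person_id").size()
    low = set(per_person[per_person < min_prompts].index)
    # persons with *zero* remaining prompts also fall below min_prompts
    zero = set(ds.persons["person_id"]) - set(per_person.index)
    removed_persons = low | zero
    kept2 = kept[~kept["person_id"].isin(removed_persons)]

    logs = [
        ExclusionLog(
            stage="prompt_compliance",
            reason=f"unanswered, delay > {max_delay} min, or all PA and stress items missing",
            n_prompts_removed=int(drop1.sum()),
            n_persons_removed=0,
        ),
        ExclusionLog(
            stage="person_min_prompts",
            reason=f"fewer than {min_prompts} compliant prompts",
            n_prompts_removed=int(len(kept) - len(kept2)),
            n_persons_removed=len(removed_persons),
        ),
    ]
    if kept2.empty:
        raise NoAnalyzableDataError("no analyzable data after compliance filtering")
    persons = ds.persons[~ds.persons["person_id"].isin(removed_persons)]
    out = ESMDataset(
        persons=persons.reset_index(drop=True),
        prompts=kept2.reset_index(drop=True),
        provenance={**ds.provenance, "compliance_filtered": True},
        issues=ds.issues,
    )
    return out, logs


def exclusion_log_frame(logs: list[ExclusionLog]) -> pd.DataFrame:
    return pd.DataFrame([vars(l) for l in logs])


def compliance_percentage(n_answered: int, n_scheduled: int) -> int:
    """Percent of scheduled prompts answered, rounded half-up to an integer.

    Half-up rounding (not banker's) matches conventional reporting of
    compliance figures such as 47/60 -> 78%.
    """
    if n_scheduled <= 0:
        raise ValueError("n_scheduled must be positive")
    if not (0 <= n_answered <= n_scheduled):
        raise ValueError("n_answered must be between 0 and n_scheduled")
    return int(np.floor(100.0 * n_answered / n_scheduled + 0.5))


def sample_totals(per_group_counts: dict) -> int:
    """Total analytic-sample (or prompt) count from per-group counts."""
    counts = list(per_group_counts.values())
    if any(c < 0 for c in counts):
        raise ValueError("counts must be nonnegative")
    return int(sum(counts))


def _anova(groups_values: list[np.ndarray]):
    """One-way ANOVA F and dfs; returns (F, df1, df2, p)."""
    f, p = stats.f_oneway(*groups_values)
    df1 = len(groups_values) - 1
    df2 = sum(len(g) for g in groups_values) - len(groups_values)
    return float(f), df1, df2, float(p)


def descriptive_table(
    ds: ESMDataset, derived: pd.DataFrame | None = None, alpha: float = 0.05
) -> dict:
    """Per-group sample descriptives with between-group tests.

    Returns a dict with a ``table`` DataFrame (one row per characteristic,
    per-group ``mean (SD)`` style columns), ``tests`` (F / chi-square with
    dfs and p), and ``contrasts`` (pairwise comparisons flagged at
    ``alpha``). ``derived`` (output of :func:`~esmstress.preprocess.derive_prompts`)
    supplies raw positive affect and composite-stress flags; without it the
    affect/stress rows are omitted.
    """
    persons = ds.persons
    groups = [g for g in GROUPS if (persons["group"] == g).any()]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for descriptives")

    answered = ds.answered()
    obs_per_person = answered.groupby("person_id").size()

    person_stats = persons.set_index("person_id").copy()
    person_stats["n_obs"] = obs_per_person.reindex(person_stats.index).fillna(0)

    if derived is not None:
        d = derived.set_index(["person_id", "day_index", "beep_index"])
        pa_mean = derived.groupby("person_id")["pa_raw"].mean()
        person_stats["pa_mean"] = pa_mean.reindex(person_stats.index)
        stressful_days = (
            derived.groupby(["person_id", "day_index"])["composite_stress"]
            .any().groupby("person_id").sum()
        )
        person_stats["stressful_days"] = stressful_days.reindex(person_stats.index).fillna(0)

    metrics = {"age": "Age", "n_obs": "Observations per person"}
    if derived is not None:
        metrics["stressful_days"] = "Stressful days per person"
        metrics["pa_mean"] = "Positive affect (raw)"
        # first composite stressor of each day (days whose first prompt is
        # already stressful carry no baseline and are skipped, mirroring the
        # trajectory exclusions); unpleasantness is reported on both candidate
        # scales since source reports are ambiguous about which was used
        d = derived.sort_values(["person_id", "day_index", "beep_index"])
        grp = d.groupby(["person_id", "day_index"])
        pos = grp.cumcount()
        first_pos = pos.where(d["composite_stress"]).groupby(
            [d["person_id"], d["day_index"]]).transform("min")
        is_first = (pos == first_pos) & (first_pos > 0)
        firsts = d[is_first].merge(
            answered[["person_id", "day_index", "beep_index", "scheduled_time"]],
            on=["person_id", "day_index", "beep_index"], how="left")
        hhmm = firsts["scheduled_time"].astype(str).str.split(":", expand=True)
        firsts["stressor_hour"] = (
            pd.to_numeric(hhmm[0], errors="coerce")
            + pd.to_numeric(hhmm[1], errors="coerce") / 60.0)
        firsts["first_unpleasantness_1to7"] = firsts["event_unpleasantness"]
        firsts["first_unpleasantness_abs_1to3"] = (
            (firsts["event_unpleasantness"] - 4.0).where(
                firsts["event_unpleasantness"] > 4.0))
        for col, label in (
            ("stressor_hour", "Time of first stressor (hour of day)"),
            ("first_unpleasantness_1to7", "Unpleasantness of first stressor (recoded 1-7)"),
            ("first_unpleasantness_abs_1to3", "Unpleasantness of first stressor (|bipolar| 1-3)"),
        ):
            pm = firsts.groupby("person_id")[col].mean()
            person_stats[col] = pm.reindex(person_stats.index)
            metrics[col] = label

    rows, tests, contrasts = [], [], []
    for col, label in metrics.items():
        cells = {}
        by_group = {}
        for g in groups:
            vals = person_stats.loc[person_stats["group"] == g, col].dropna().to_numpy()
            by_group[g] = vals
            if len(vals) >= 2:
                cells[g] = f"{np.mean(vals):.2f} ({np.std(vals, ddof=1):.2f})"
            elif len(vals) == 1:
                cells[g] = f"{vals[0]:.2f} (undefined)"
            else:
                cells[g] = "n/a"
        rows.append({"characteristic": label, **cells})
        if any(len(v) < 2 for v in by_group.values()):
            warnings.warn(f"group with n < 2: skipping test for {label}")
            continue
        f, df1, df2, p = _anova([by_group[g] for g in groups])
        tests.append({"characteristic": label, "test": "anova_F",
                      "statistic": f, "df1": df1, "df2": df2, "p": p})
        for g1, g2 in combinations(groups, 2):
            t, pp = stats.ttest_ind(by_group[g1], by_group[g2])
            contrasts.append({"characteristic": label, "pair": f"{g1} vs {g2}",
                              "statistic": float(t), "p": float(pp),
                              "significant": bool(pp < alpha)})

    # gender composition
    counts = pd.crosstab(persons["group"], persons["gender"]).reindex(groups)
    for gender in counts.columns:
        rows.append({"characteristic": f"Gender: {gender}, n",
                     **{g: str(int(counts.loc[g, gender])) for g in groups}})
    if (persons.groupby("group").size() >= 2).all() and counts.shape[1] > 1:
        chi2, p, dof, _ = stats.chi2_contingency(counts.to_numpy(), correction=False)
        tests.append({"characteristic": "Gender", "test": "chi_square",
                      "statistic": float(chi2), "df1": int(dof), "df2": np.nan,
                      "p": float(p)})

    return {
        "table": pd.DataFrame(rows),
        "tests": pd.DataFrame(
            tests, columns=["characteristic", "test", "statistic", "df1", "df2", "p"]),
        "contrasts": pd.DataFrame(
            contrasts, columns=["characteristic", "pair", "statistic", "p", "significant"]),
        "group_n": persons.groupby("group").size().reindex(groups).to_dict(),
    }
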