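"""Scoring of momentary positive affect and the three stress measures.

Positive affect (PA) is the mean of three 1–7 items (cheerful, relaxed,
satisfied). Event-related stress comes from a bipolar pleasantness rating
of the most important recent event (−3 very unpleasant .. +3 very
pleasant), recoded to 1–7 unpleasantness; activity-related stress from
four 1–7 activity appraisal items with "skilled" reverse coded. The
composite stress measure is the presence of either type (logical OR).

Dichotomization thresholds are not canonical and are config-exposed: the
defaults flag an event as stressful when the recoded unpleasantness
exceeds the scale midpoint (i.e. the original bipolar rating was
negative) and an activity as stressful when the appraisal mean exceeds
the midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ACT_ITEMS, PA_ITEMS, ESMDataset


@dataclass
class StressThresholds:
    """Strict lower bounds on the 1–7 scores above which stress is flagged."""

    event: float = 4.0
    activity: float = 4.0


def score_positive_affect(items) -> float:
    """Mean of the 3 PA items; missing unless at least 2 items answered."""
    vals = np.asarray([np.nan if v is None else v for v in items], dtype=float)
    ok = ~np.isnan(vals)
    if (vals[ok] < 1).any() or (vals[ok] > 7).any():
        raise ValueError("PA items must be in 1..7")
    if ok.sum() < 2:
        return np.nan
    return float(vals[ok].mean())


def recode_event_unpleasantness(x: float) -> float:
    """Map bipolar pleasantness −3..+3 to unpleasantness 1..7 (y = 4 − x)."""
    if np.isnan(x):
        return np.nan
    if not -3 <= x <= 3:
        raise ValueError(f"event pleasantness out of range: {x}")
    return 4.0 - x


def score_activity(items) -> float:
    """Mean of the 4 activity items after reverse-coding 'skilled'.

    ``items`` are (energy, skilled, challenge, prefer_else) on 1–7;
    skilled is replaced by 8 − skilled. Missing unless ≥ 2 items answered.
    """
    vals = np.asarray([np.nan if v is None else v for v in items], dtype=float)
    if len(vals) != 4:
        raise ValueError("expected 4 activity items")
    ok = ~np.isnan(vals)
    if (vals[ok] < 1).any() or (vals[ok] > 7).any():
        raise ValueError("activity items must be in 1..7")
    if not np.isnan(vals[1]):
        vals[1] = 8.0 - vals[1]
    if ok.sum() < 2:
        return np.nan
    return float(vals[~np.isnan(vals)].mean())


def flag_stress(
    derived: pd.DataFrame, thresholds: StressThresholds | None = None
) -> pd.DataFrame:
    """Dichotomize the stress scores and build the composite measure.

    Adds boolean columns ``event_stress``, ``activity_stress``,
    ``composite_stress`` plus ``*_missing`` markers. A missing score gives
    flag False with its missingness marker True; the composite is the OR
    of the defined flags and is missing only when both are missing.
    """
    th = thresholds or StressThresholds()
    out = derived.copy()
    ev, ac = out["event_unpleasantness"], out["activity_score"]
    out["event_stress_missing"] = ev.isna()
    out["activity_stress_missing"] = ac.isna()
    out["event_stress"] = (ev > th.event).fillna(False)
    out["activity_stress"] = (ac > th.activity).fillna(False)
    out["composite_stress"] = out["event_stress"] | out["activity_stress"]
    out["composite_stress_missing"] = (
        out["event_stress_missing"] & out["activity_stress_missing"]
    )
    return out


def derive_prompts(
    ds: ESMDataset, thresholds: StressThresholds | None = None
) -> pd.DataFrame:
    """Score every answered prompt: PA, stress measures and flags.

    Returns one row per answered prompt with keys
    (person_id, day_index, beep_index) plus derived columns. Vectorized
    equivalents of the per-prompt scoring functions are used; the scalar
    functions remain the reference semantics.
    """
    p = ds.answered().copy()

    pa = p[PA_ITEMS]
    n_pa = pa.notna().sum(axis=1)
    p["pa_raw"] = pa.mean(axis=1).where(n_pa >= 2)

    bad = p["event_pleasantness"].notna() & (
        (p["event_pleasantness"] < -3) | (p["event_pleasantness"] > 3)
    )
    if bad.any():
        raise ValueError("event_pleasantness out of range −3..3")
    p["event_unpleasantness"] = 4.0 - p["event_pleasantness"]

    act = p[ACT_ITEMS].copy()
    act["act_skilled"] = 8.0 - act["act_skilled"]
    n_act = act.notna().sum(axis=1)
    p["activity_score"] = act.mean(axis=1).where(n_act >= 2)

    keep = ["person_id", "group", "age", "gender", "day_index", "beep_index",
            "pa_raw", "event_unpleasantness", "activity_score"]
    return flag_stress(p[keep].reset_index(drop=True), thresholds)


def center_and_standardize(derived: pd.DataFrame) -> pd.DataFrame:
    """Doubly demean PA within person then person-day, and z-standardize.

    Subtracts each person's mean ``pa_raw``, then each person-day's mean of
    the person-centered values, and divides by the overall SD of the
    doubly-centered values, so the resulting ``pa_z`` has mean 0 and SD 1
    overall and mean 0 within every person and person-day. Persons with a
    single PA prompt are excluded from centering (pa_z missing) with a
    warning. If the doubly-centered values are constant the SD guard
    returns zeros with a warning.

    Note this transform removes *all* between-person level differences;
    for analyses of group differences in affect level, use
    :func:`standardize_grand` (the pipeline default).
    """
    out = derived.copy()
    n_per_person = out.groupby("person_id")["pa_raw"].transform("count")
    single = n_per_person < 2
    if single.any():
        warnings.warn(
            f"{out.loc[single, 'person_id'].nunique()} person(s) with a single "
            "PA prompt excluded from centering"
        )
    x = out["pa_raw"].where(~single)
    x = x - x.groupby(out["person_id"]).transform("mean")
    x = x - x.groupby([out["person_id"], out["day_index"]]).transform("mean")
    sd = x.std(ddof=0)
    if not np.isfinite(sd) or sd < 1e-12:
        warnings.warn("doubly-centered PA has zero variance; pa_z set to 0")
        out["pa_z"] = x * 0.0
    else:
        out["pa_z"] = x / sd
    return out


def standardize_grand(derived: pd.DataFrame) -> pd.DataFrame:
    """z-standardize ``pa_raw`` with the grand mean and SD (location/scale only).

    Person and day means are left in the data and are absorbed by the
    random intercepts of the three-level model, so between-group level
    differences remain estimable.
    """
    out = derived.copy()
    x = out["pa_raw"]
    sd = x.std(ddof=0)
    if not np.isfinite(sd) or sd < 1e-12:
        warnings.warn("PA has zero variance; pa_z set to 0")
        out["pa_z"] = (x - x.mean()) * 0.0
    else:
        out["pa_z"] = (x - x.mean()) / sd
    return out


@dataclass
class PcaReport:
    loadings: pd.DataFrame
    variance_explained: np.ndarray
    n_components_retained: int
    warning: str | None = None


def pca_justification(
    ds_or_derived, eigenvalue_threshold: float = 1.0
) -> PcaReport:
    """Principal components of the 5 stress indicators on the correlation scale.

    The indicators are recoded event unpleasantness and the four activity
    items (skilled reverse-coded). Components are retained by the
    eigenvalue > ``eigenvalue_threshold`` rule. A singular correlation
    matrix yields a report carrying a warning and no retention decision.
    """
    if isinstance(ds_or_derived, ESMDataset):
        p = ds_or_derived.answered().copy()
        items = pd.DataFrame({
            "event_unpleasantness": 4.0 - p["event_pleasantness"],
            "act_energy": p["act_energy"],
            "act_skilled_rev": 8.0 - p["act_skilled"],
            "act_challenge": p["act_challenge"],
            "act_prefer_else": p["act_prefer_else"],
        })
    else:
        items = pd.DataFrame(ds_or_derived)
    items = items.dropna()
    if len(items) < 50:
        raise ValueError("need at least 50 complete prompts for the PCA check")

    corr = np.corrcoef(items.to_numpy(), rowvar=False)
    if not np.all(np.isfinite(corr)):
        return PcaReport(
            loadings=pd.DataFrame(index=items.columns),
            variance_explained=np.array([]),
            n_components_retained=0,
            warning="singular correlation matrix (a constant indicator?)",
        )
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    var_explained = eigvals / eigvals.sum()
    n_keep = int((eigvals > eigenvalue_threshold).sum())
    loadings = pd.DataFrame(
        eigvecs, index=items.columns,
        columns=[f"PC{i + 1}" for i in range(len(eigvals))],
    )
    return PcaReport(loadings, var_explained, n_keep)
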