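"""End-to-end orchestration: compliance filter → scoring → trajectory
coding → H1–H4 mixed models → Simes flags → publication-style tables.

The hypothesis sequence mirrors the staging analysis: H1 within-group
reactivity/recovery (separate model per group), H2 group main effect and
baseline contrasts, H3 time_since × group interaction at t0, H4
between-group contrast of the average deviation from baseline over the
recovery window, plus a sensitivity variant controlling for subsequent
stressors. Every threshold is a config field so variants (e.g. the
unadjusted models) are a single flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data as esm_data
from . import mlm, preprocess, trajectory
from .data import ESMDataset

STRESS_TYPES = ("event", "activity", "composite")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline aborted at stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    input: str | None = None
    outdir: str = "results"
    max_delay: float = 15.0
    min_prompts: int = 20
    event_threshold: float = 4.0
    activity_threshold: float = 4.0
    max_lag: dict = field(default_factory=lambda: dict(trajectory.DEFAULT_MAX_LAG))
    covariates: bool = True
    sensitivity: bool = True
    centering: str = "grand"      # "grand" or "person_day"
    estimation: str = "ML"
    alpha: float = 0.05
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.centering not in ("grand", "person_day"):
            raise ValueError("centering must be 'grand' or 'person_day'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _contrast_row(c: mlm.Contrast, **extra) -> dict:
    return {**extra, "term": c.label, "b": c.b, "ci_low": c.ci_low,
            "ci_high": c.ci_high, "p": c.p, "note": c.note}


def prepare_derived(ds: ESMDataset, config: RunConfig) -> pd.DataFrame:
    """Score and standardize the filtered dataset."""
    th = preprocess.StressThresholds(config.event_threshold, config.activity_threshold)
    derived = preprocess.derive_prompts(ds, th)
    if config.centering == "grand":
        return preprocess.standardize_grand(derived)
    return preprocess.center_and_standardize(derived)


def build_frame(derived: pd.DataFrame, stress_type: str, max_lag: int) -> pd.DataFrame:
    """Trajectory-coded analysis frame for one stress measure."""
    coded = trajectory.code_time_since(derived, stress_type, max_lag)
    return trajectory.flag_subsequent_stress(coded)


def _simes_flags(records: list[dict], alpha: float) -> None:
    """Annotate rows sharing a family key with Simes flags in place.

    A family is one hypothesis repeated across the stress measures; the
    step thresholds adapt to the number of members (3, or 2 when a
    measure has no such contrast, e.g. no recovery window for event
    stress).
    """
    byfam: dict = {}
    for r in records:
        byfam.setdefault(r["family"], []).append(r)
    for fam, rows in byfam.items():
        ok = [r for r in rows if np.isfinite(r.get("p", np.nan))]
        m = len(ok)
        if m == 0:
            continue
        thresholds = mlm._simes_thresholds(m, alpha)
        order = np.argsort([r["p"] for r in ok], kind="stable")
        for rank, i in enumerate(order):
            ok[i]["simes_significant"] = bool(ok[i]["p"] <= thresholds[rank])


def analyze(ds: ESMDataset, config: RunConfig | None = None) -> dict:
    """Run the full analysis in memory; returns tables and fit objects."""
    config = config or RunConfig()
    out: dict = {"config": config}

    stage = "compliance_filter"
    try:
        filtered, logs = esm_data.apply_compliance_filter(
            ds, config.max_delay, config.min_prompts)
        out["exclusion_log"] = esm_data.exclusion_log_frame(logs)

        stage = "preprocess"
        derived = prepare_derived(filtered, config)
        out["derived"] = derived

        stage = "descriptives"
        out["table1"] = esm_data.descriptive_table(filtered, derived, config.alpha)

        stage = "pca_justification"
        try:
            out["pca"] = preprocess.pca_justification(filtered)
        except ValueError as exc:
            warnings.warn(f"composite-measure PCA check skipped: {exc}")
            out["pca"] = None

        t2_rows, t3_rows, t4_rows, margin_rows, excl_rows = [], [], [], [], []
        fits: dict = {}
        group_effects: list[dict] = []

        for st in STRESS_TYPES:
            stage = f"trajectory_{st}"
            K = config.max_lag[st]
            frame = build_frame(derived, st, K)
            summ = trajectory.exclusion_summary(frame)
            excl_rows.append(vars(summ))

            stage = f"h1_models_{st}"
            within: dict = {}
            for g in [g for g in mlm.GROUP_ORDER if g in set(frame["group"])]:
                spec = mlm.ModelSpec(stress_type=st, groups=(g,),
                                     covariates=config.covariates,
                                     estimation=config.estimation)
                fit = mlm.fit_lmm(frame, spec)
                fits[(st, "h1", g)] = fit
                cons = mlm.within_group_contrasts(fit)
                within[g] = cons
                for c in cons:
                    t2_rows.append(_contrast_row(
                        c, stress_type=st, group=g,
                        family=f"within:{g}:{c.label}"))
                for cov in ("age_c", "female"):
                    if cov in fit.beta.index:
                        t2_rows.append(_contrast_row(
                            mlm.linear_contrast(fit, {cov: 1.0}, cov),
                            stress_type=st, group=g, family=f"within:{g}:{cov}"))
                if config.sensitivity:
                    sfit = mlm.fit_lmm(frame, mlm.ModelSpec(
                        stress_type=st, groups=(g,), covariates=config.covariates,
                        subsequent_stress_control=True,
                        estimation=config.estimation))
                    fits[(st, "h1s", g)] = sfit
                    for c in mlm.within_group_contrasts(sfit):
                        t3_rows.append(_contrast_row(
                            c, stress_type=st, group=g,
                            family=f"within_s:{g}:{c.label}"))
                    t3_rows.append(_contrast_row(
                        mlm.linear_contrast(
                            sfit, {"subsequent_stress01": 1.0}, "subsequent_stress"),
                        stress_type=st, group=g,
                        family=f"within_s:{g}:subsequent"))

            stage = f"h2_h4_models_{st}"
            main_spec = mlm.ModelSpec(stress_type=st, include_group_terms=True,
                                      covariates=config.covariates,
                                      estimation=config.estimation)
            main_fit = mlm.fit_lmm(frame, main_spec)
            fits[(st, "h2")] = main_fit
            if main_fit.converged:
                ge = mlm.group_main_effect(main_fit)
                group_effects.append({"stress_type": st, **ge, "family": "group_main"})

            int_spec = mlm.ModelSpec(stress_type=st, include_group_terms=True,
                                     include_interaction=True,
                                     covariates=config.covariates,
                                     estimation=config.estimation)
            int_fit = mlm.fit_lmm(frame, int_spec)
            fits[(st, "h3")] = int_fit

            for tp in ("t-1", "t0"):
                for c in mlm.between_group_contrasts(int_fit, tp):
                    pair = c.label.split(" at ")[0]
                    t4_rows.append(_contrast_row(
                        c, stress_type=st, pair=pair, timepoint=tp,
                        family=f"between:{pair}:{tp}"))

            stage = f"recovery_{st}"
            followups = {
                g: [c for c in cons if c.label.startswith("t") and c.label not in ("t-1", "t0")]
                for g, cons in within.items()
            }
            try:
                win = mlm.recovery_window(followups, config.alpha)
            except ValueError:
                win = None
            out.setdefault("recovery_windows", {})[st] = win
            if win and win["window"] and max(win["window"]) <= K:
                for pair in mlm.PAIRS:
                    if all(p in int_fit.group_levels for p in pair):
                        c = mlm.recovery_contrast(int_fit, win["window"], pair)
                        t4_rows.append(_contrast_row(
                            c, stress_type=st, pair=f"{pair[0]} vs {pair[1]}",
                            timepoint=f"t1-t{max(win['window'])}",
                            family=f"between:{pair[0]} vs {pair[1]}:recovery"))

            stage = f"margins_{st}"
            if int_fit.converged:
                m = mlm.adjusted_margins(int_fit)
                m.insert(0, "stress_type", st)
                margin_rows.append(m)

        stage = "simes"
        _simes_flags(t2_rows, config.alpha)
        _simes_flags(t3_rows, config.alpha)
        _simes_flags(t4_rows, config.alpha)
        _simes_flags(group_effects, config.alpha)

        out["table2"] = pd.DataFrame(t2_rows)
        out["table3"] = pd.DataFrame(t3_rows)
        out["table4"] = pd.DataFrame(t4_rows)
        out["group_effects"] = pd.DataFrame(group_effects)
        out["margins"] = (pd.concat(margin_rows, ignore_index=True)
                          if margin_rows else pd.DataFrame())
        out["exclusion_summaries"] = pd.DataFrame(excl_rows)
        out["fits"] = fits

        stage = "summary"
        out["summary"] = _summarize(ds, filtered, out, config)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
    return out


def _summarize(raw: ESMDataset, filtered: ESMDataset, out: dict,
               config: RunConfig) -> dict:
    log = out["exclusion_log"]
    n_removed = int(log["n_prompts_removed"].sum())
    summary = {
        "config": {k: v for k, v in asdict(config).items()},
        "input": {"n_persons": int(raw.n_persons), "n_prompts": int(raw.n_prompts)},
        "analytic": {
            "n_persons": int(filtered.n_persons),
            "n_prompts": int(filtered.n_prompts),
            "n_prompts_removed": n_removed,
            "reconciles": bool(raw.n_prompts == filtered.n_prompts + n_removed),
        },
        "compliance_percent": {},
        "group_n": {k: int(v) for k, v in out["table1"]["group_n"].items()},
        "recovery_windows": {
            st: (None if w is None else
                 {"per_group": {g: int(l) for g, l in w["per_group"].items()},
                  "window": [int(k) for k in w["window"]]})
            for st, w in out.get("recovery_windows", {}).items()
        },
        "design_decisions": {
            "event_threshold": config.event_threshold,
            "activity_threshold": config.activity_threshold,
            "max_lag": {k: int(v) for k, v in config.max_lag.items()},
            "centering": config.centering,
            "estimation": config.estimation,
            "min_items_for_score": 2,
            "simes_thresholds_3": [round(t, 4) for t in mlm._simes_thresholds(3, config.alpha)],
        },
    }
    scheduled = raw.provenance.get("n_days", 6) * raw.provenance.get("n_beeps_per_day", 10)
    answered = raw.answered().groupby("person_id").size()
    per_group = raw.persons.set_index("person_id")["group"]
    for g in sorted(per_group.unique()):
        ids = per_group[per_group == g].index
        mean_answered = float(answered.reindex(ids).fillna(0).mean())
        summary["compliance_percent"][g] = esm_data.compliance_percentage(
            int(round(mean_answered)), scheduled)
    return summary


def run_pipeline(config: RunConfig, ds: ESMDataset | None = None) -> dict:
    """Run :func:`analyze` and write all artifacts under ``config.outdir``.

    Any stage error aborts with the stage name; artifacts written before
    the failure are preserved on disk.
    """
    if ds is None:
        if config.input is None:
            raise ValueError("RunConfig.input or an in-memory dataset is required")
        ds = esm_data.read_esm_long(config.input)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    res = analyze(ds, config)

    res["table1"]["table"].to_csv(outdir / "table1_descriptives.csv", index=False)
    res["table1"]["tests"].to_csv(outdir / "table1_tests.csv", index=False)
    res["table2"].to_csv(outdir / "table2_within_group.csv", index=False)
    if len(res["table3"]):
        res["table3"].to_csv(outdir / "table3_sensitivity.csv", index=False)
    res["table4"].to_csv(outdir / "table4_between_group.csv", index=False)
    res["group_effects"].to_csv(outdir / "group_main_effects.csv", index=False)
    res["margins"].to_csv(outdir / "margins.csv", index=False)
    if res.get("pca") is not None:
        pca = res["pca"]
        rep = pca.loadings.copy()
        rep.loc["variance_explained"] = pca.variance_explained
        rep.to_csv(outdir / "pca_stress_indicators.csv")
    res["exclusion_log"].to_csv(outdir / "exclusion_log.csv", index=False)
    res["exclusion_summaries"].to_csv(outdir / "exclusion_summaries.csv", index=False)
    with open(outdir / "summary.yaml", "w") as fh:
        yaml.safe_dump(res["summary"], fh, sort_keys=True)
    if config.verbosity:
        s = res["summary"]["analytic"]
        print(f"analytic sample: {s['n_persons']} persons, {s['n_prompts']} prompts "
              f"({s['n_prompts_removed']} prompts removed)")
    return res
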