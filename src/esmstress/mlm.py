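"""Three-level linear mixed models for affect trajectories, and the
reactivity / baseline / recovery contrasts built on them.

The model is

    pa_z ~ time_since (+ group + time_since x group) (+ age_c + female)
           (+ subsequent_stress)

with random intercepts for person (level 3) and day-within-person
(level 2), estimated by maximum likelihood (REML optional). Inference is
large-sample Wald: 95% CIs use the normal critical value and p-values the
z statistic, matching the conventions of mixed-model software that
reports z/chi-square tests. Baseline t−1 is always the reference time
category and 'control' the reference group when present.

Multiplicity across the three stress measures is handled by the Simes
step rule: the smallest of the three p-values is compared with α/3, the
second with α/2, the largest with α.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

GROUP_ORDER = ("control", "at_risk", "patient")
PAIRS = (("at_risk", "control"), ("patient", "control"), ("patient", "at_risk"))

Z95 = stats.norm.ppf(0.975)


@dataclass
class ModelSpec:
    """Configuration of one mixed-model fit."""

    stress_type: str = "composite"
    groups: tuple | None = None          # None = all groups present
    include_group_terms: bool = False
    include_interaction: bool = False
    covariates: bool = True              # age (grand-mean centered) + gender
    subsequent_stress_control: bool = False
    estimation: str = "ML"               # or "REML"
    random_slope_t0: bool = False
    reference_group: str = "control"

    def __post_init__(self) -> None:
        if self.include_interaction and not self.include_group_terms:
            raise ValueError("interaction requires group terms")
        if self.estimation not in ("ML", "REML"):
            raise ValueError("estimation must be 'ML' or 'REML'")


@dataclass
class FitResult:
    """Fixed effects, their covariance, and variance components of one fit."""

    beta: pd.Series
    vcov: pd.DataFrame
    var_person: float
    var_day: float
    var_resid: float
    loglik: float
    converged: bool
    n_obs: int
    n_days: int
    n_persons: int
    time_levels: list
    group_levels: list
    spec: ModelSpec
    diagnostics: str = ""

    def time_term(self, label: str) -> str:
        return f"ts_{label.replace('-', 'm')}"

    def group_term(self, g: str) -> str:
        return f"g_{g}"

    def interaction_term(self, g: str, label: str) -> str:
        return f"{self.group_term(g)}__{self.time_term(label)}"


@dataclass
class Contrast:
    label: str
    b: float
    ci_low: float
    ci_high: float
    p: float
    se: float = np.nan
    note: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.b) and not (self.ci_low <= self.b <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


def _sorted_time_levels(values) -> list:
    def key(lab):
        return -1 if lab == "t-1" else int(lab[1:])
    return sorted(set(values), key=key)


def build_design(frame: pd.DataFrame, spec: ModelSpec):
    """Assemble the analysis frame with explicit dummy columns.

    Returns (data, fixed_terms, time_levels, group_levels). ``frame`` must
    contain included trajectory rows joined to pa_z and covariates.
    """
    data = frame.loc[frame["included"]].copy()
    if spec.groups is not None:
        data = data[data["group"].isin(spec.groups)]
    data = data.dropna(subset=["pa_z"])
    if data.empty:
        raise ValueError("no rows to fit")

    time_levels = _sorted_time_levels(data["time_since"])
    if "t-1" not in time_levels:
        raise ValueError("reference level t-1 absent from the data")
    group_levels = [g for g in GROUP_ORDER if g in set(data["group"])]

    terms = []
    for lab in time_levels:
        if lab == "t-1":
            continue
        c = f"ts_{lab.replace('-', 'm')}"
        data[c] = (data["time_since"] == lab).astype(float)
        terms.append(c)

    if spec.include_group_terms:
        ref = spec.reference_group if spec.reference_group in group_levels else group_levels[0]
        for g in group_levels:
            if g == ref:
                continue
            gc = f"g_{g}"
            data[gc] = (data["group"] == g).astype(float)
            terms.append(gc)
            if spec.include_interaction:
                for lab in time_levels:
                    if lab == "t-1":
                        continue
                    tc = f"ts_{lab.replace('-', 'm')}"
                    ic = f"{gc}__{tc}"
                    data[ic] = data[gc] * data[tc]
                    terms.append(ic)

    if spec.covariates:
        person_age = data.drop_duplicates("person_id")["age"]
        data["age_c"] = data["age"] - person_age.mean()
        data["female"] = (data["gender"] == "female").astype(float)
        terms += ["age_c", "female"]

    if spec.subsequent_stress_control:
        ss = data.get("subsequent_stress")
        if ss is None:
            raise ValueError("frame lacks subsequent_stress; run flag_subsequent_stress")
        # indicator applies at t1..tK only; structurally 0 at t-1/t0
        data["subsequent_stress01"] = ss.fillna(False).astype(float)
        terms.append("subsequent_stress01")

    return data, terms, time_levels, group_levels


def fit_lmm(frame: pd.DataFrame, spec: ModelSpec | None = None) -> FitResult:
    """Fit the three-level random-intercept model by (RE)ML.

    Non-convergence is reported (``converged=False`` with diagnostics),
    never silently replaced by a simpler model.
    """
    spec = spec or ModelSpec()
    data, terms, time_levels, group_levels = build_design(frame, spec)

    formula = "pa_z ~ " + (" + ".join(terms) if terms else "1")
    re_formula = "1"
    if spec.random_slope_t0 and "ts_t0" in data:
        re_formula = "1 + ts_t0"

    diagnostics = ""
    converged = False
    try:
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always", ConvergenceWarning)
            model = smf.mixedlm(
                formula, data, groups=data["person_id"],
                re_formula=re_formula,
                vc_formula={"day": "0 + C(day_index)"},
            )
            reml = spec.estimation == "REML"
            # boundary-ish variance components trip lbfgs now and then;
            # fall back to slower optimizers before declaring failure
            res = None
            for method in ("lbfgs", "bfgs", "powell"):
                try:
                    res = model.fit(reml=reml, method=method, maxiter=200)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if res.converged:
                    break
            if res is None:
                raise RuntimeError("all optimizers failed")
            converged = bool(res.converged)
            diagnostics = "; ".join(str(w.message) for w in wrec
                                    if issubclass(w.category, ConvergenceWarning))
    except Exception as exc:  # pragma: no cover - defensive
        return FitResult(
            beta=pd.Series(dtype=float), vcov=pd.DataFrame(),
            var_person=np.nan, var_day=np.nan, var_resid=np.nan,
            loglik=np.nan, converged=False,
            n_obs=len(data), n_days=data.groupby(["person_id", "day_index"]).ngroups,
            n_persons=data["person_id"].nunique(),
            time_levels=time_levels, group_levels=group_levels,
            spec=spec, diagnostics=f"fit failed: {exc}",
        )

    k_fe = len(res.fe_params)
    return FitResult(
        beta=res.fe_params.copy(),
        vcov=pd.DataFrame(
            np.asarray(res.cov_params())[:k_fe, :k_fe],
            index=res.fe_params.index, columns=res.fe_params.index,
        ),
        var_person=float(np.asarray(res.cov_re)[0, 0]),
        var_day=float(res.vcomp[0]) if len(res.vcomp) else 0.0,
        var_resid=float(res.scale),
        loglik=float(res.llf),
        converged=converged,
        n_obs=len(data),
        n_days=int(data.groupby(["person_id", "day_index"]).ngroups),
        n_persons=int(data["person_id"].nunique()),
        time_levels=time_levels,
        group_levels=group_levels,
        spec=spec,
        diagnostics=diagnostics,
    )


def linear_contrast(fit: FitResult, weights: dict, label: str) -> Contrast:
    """Wald contrast for a linear combination of fixed effects."""
    if not fit.converged:
        return Contrast(label, np.nan, np.nan, np.nan, np.nan,
                        note="model did not converge")
    missing = [t for t in weights if t not in fit.beta.index]
    if missing:
        return Contrast(label, np.nan, np.nan, np.nan, np.nan,
                        note=f"term(s) absent from model: {missing}")
    L = pd.Series(0.0, index=fit.beta.index)
    for term, w in weights.items():
        L[term] = w
    b = float(L @ fit.beta)
    se = float(np.sqrt(L @ fit.vcov @ L))
    z = b / se if se > 0 else np.nan
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return Contrast(label, b, b - Z95 * se, b + Z95 * se, p, se=se)


def within_group_contrasts(fit: FitResult, timepoints=None) -> list[Contrast]:
    """Deviation of each post-baseline time point from baseline t−1.

    With t−1 as reference, each contrast is simply the coefficient of the
    corresponding time dummy. Requested time points absent from the model
    yield a labeled-gap result rather than a silent skip.
    """
    if timepoints is None:
        timepoints = [t for t in fit.time_levels if t != "t-1"]
    return [linear_contrast(fit, {fit.time_term(t): 1.0}, t) for t in timepoints]


def group_main_effect(fit: FitResult):
    """Joint Wald chi-square that all group coefficients are zero.

    Interaction terms, if present, are not part of this test; df equals
    the number of group dummies.
    """
    terms = [fit.group_term(g) for g in fit.group_levels
             if fit.group_term(g) in fit.beta.index]
    if not terms:
        raise ValueError("fit has no group terms")
    b = fit.beta[terms].to_numpy()
    V = fit.vcov.loc[terms, terms].to_numpy()
    try:
        chi2 = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular covariance among group terms {terms}") from exc
    df = len(terms)
    return {"chi2": chi2, "df": df, "p": float(stats.chi2.sf(chi2, df))}


def between_group_contrasts(
    fit: FitResult, timepoint: str = "t-1", level_difference: bool = False
) -> list[Contrast]:
    """Pairwise group contrasts at one time point.

    At baseline (t−1, the reference category) the contrast is the
    group-dummy difference: the gap in expected pa_z between the groups.
    At t0 and later the contrast is the difference in *deviation from
    baseline* — the time_since × group interaction — i.e. the group
    difference in reactivity, which is the quantity the staging
    comparison tables report. Set ``level_difference=True`` to add the
    group dummies and obtain the absolute level gap at that time point
    instead.
    """
    ref = fit.spec.reference_group
    out = []
    for a, bg in PAIRS:
        if a not in fit.group_levels or bg not in fit.group_levels:
            continue
        w: dict = {}
        for g, sgn in ((a, 1.0), (bg, -1.0)):
            if g == ref:
                continue
            if timepoint == "t-1" or level_difference:
                w[fit.group_term(g)] = w.get(fit.group_term(g), 0.0) + sgn
            if timepoint != "t-1":
                term = fit.interaction_term(g, timepoint)
                w[term] = w.get(term, 0.0) + sgn
        out.append(linear_contrast(fit, w, f"{a} vs {bg} at {timepoint}"))
    return out


def recovery_window(
    within: dict[str, list[Contrast]], alpha: float = 0.05
) -> dict:
    """Locate per-group recovery points and the common recovery window.

    ``within`` maps group -> contrasts for t1..tK (ordered). The group's
    recovery point L_g is the first lag whose deviation from baseline is
    no longer significant at ``alpha`` (K+1 if none). The common window
    runs t1..t_max(L_g): the latest first-recovered prompt marks the end
    of the continuous recovery period, capped at the modeled horizon.
    """
    if not within:
        raise ValueError("no contrast sequences supplied")
    per_group = {}
    K = 0
    for g, contrasts in within.items():
        if not contrasts:
            raise ValueError(f"empty contrast sequence for group {g}")
        K = max(K, len(contrasts))
        L = len(contrasts) + 1
        for k, c in enumerate(contrasts, start=1):
            if not np.isfinite(c.p):
                raise ValueError(f"missing p-value at lag {k} for group {g}")
            if c.p >= alpha:
                L = k
                break
        per_group[g] = L
    end = min(max(per_group.values()), K)
    return {"per_group": per_group, "window": list(range(1, end + 1))}


def recovery_contrast(fit: FitResult, window: list[int], pair) -> Contrast:
    """Between-group difference in mean deviation from baseline over the
    recovery window (the average of the window's interaction coefficients)."""
    if not window:
        raise ValueError("empty recovery window")
    modeled = {int(t[1:]) for t in fit.time_levels if t not in ("t-1",)}
    beyond = [k for k in window if k not in modeled]
    if beyond:
        raise ValueError(f"window lags {beyond} beyond modeled horizon {sorted(modeled)}")
    a, bg = pair
    ref = fit.spec.reference_group
    w: dict = {}
    for g, sgn in ((a, 1.0), (bg, -1.0)):
        if g == ref:
            continue
        for k in window:
            term = fit.interaction_term(g, f"t{k}")
            w[term] = w.get(term, 0.0) + sgn / len(window)
    lab = f"{a} vs {bg} recovery t1-t{max(window)}"
    return linear_contrast(fit, w, lab)


def within_recovery_deviation(fit: FitResult, window: list[int], group: str) -> Contrast:
    """Average deviation from baseline over the window, within one group."""
    ref = fit.spec.reference_group
    w: dict = {}
    for k in window:
        w[fit.time_term(f"t{k}")] = w.get(fit.time_term(f"t{k}"), 0.0) + 1.0 / len(window)
        if group != ref and fit.interaction_term(group, f"t{k}") in fit.beta.index:
            w[fit.interaction_term(group, f"t{k}")] = 1.0 / len(window)
    return linear_contrast(fit, w, f"{group} mean deviation t1-t{max(window)}")


def adjusted_margins(fit: FitResult, female_at: float | None = None) -> pd.DataFrame:
    """Model-based expected pa_z per group x time at adjusted covariates.

    Age enters at its grand-mean-centered value 0; gender at ``female_at``
    (defaults to 0.5, an equal mix). These are the quantities plotted as
    trajectory figures with 95% CI error bars.
    """
    if female_at is None:
        female_at = 0.5
    rows = []
    for g in fit.group_levels:
        for t in fit.time_levels:
            w = {"Intercept": 1.0}
            if t != "t-1":
                w[fit.time_term(t)] = 1.0
            if g != fit.spec.reference_group and fit.group_term(g) in fit.beta.index:
                w[fit.group_term(g)] = 1.0
                it = fit.interaction_term(g, t)
                if t != "t-1" and it in fit.beta.index:
                    w[it] = 1.0
            if "female" in fit.beta.index:
                w["female"] = female_at
            c = linear_contrast(fit, w, f"{g}@{t}")
            rows.append({"group": g, "time_since": t, "margin": c.b,
                         "ci_low": c.ci_low, "ci_high": c.ci_high})
    return pd.DataFrame(rows)


@dataclass
class SimesOutcome:
    p_values: tuple
    thresholds: tuple            # per ascending rank, exact
    thresholds_rounded: tuple    # per ascending rank, 2 decimals
    significant: tuple           # in the original order of p_values
    family_alpha: float = 0.05


def _simes_thresholds(m: int, family_alpha: float) -> list[float]:
    """Step thresholds for the r-th smallest of m p-values: alpha/(m−r+1)."""
    return [family_alpha / (m - r) for r in range(m)]


def simes_correct(p_values, family_alpha: float = 0.05) -> SimesOutcome:
    """Simes step rule over the three stress measures.

    The smallest p is compared with alpha/3, the middle with alpha/2, the
    largest with alpha. Flags are returned in the original order.
    """
    p = tuple(float(x) for x in p_values)
    if len(p) != 3:
        raise ValueError("simes_correct expects exactly 3 p-values (one per stress measure)")
    if any(not (0 < x <= 1) for x in p):
        raise ValueError("p-values must lie in (0, 1]")
    thresholds = _simes_thresholds(3, family_alpha)
    order = np.argsort(p, kind="stable")
    sig = [False, False, False]
    for rank, idx in enumerate(order):
        sig[idx] = p[idx] <= thresholds[rank]
    return SimesOutcome(
        p_values=p,
        thresholds=tuple(thresholds),
        thresholds_rounded=tuple(round(t, 2) for t in thresholds),
        significant=tuple(sig),
        family_alpha=family_alpha,
    )
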