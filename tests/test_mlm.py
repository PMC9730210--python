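import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from esmstress import (
    Contrast,
    FitResult,
    ModelSpec,
    adjusted_margins,
    apply_compliance_filter,
    between_group_contrasts,
    derive_prompts,
    fit_lmm,
    generate,
    group_main_effect,
    recovery_contrast,
    recovery_window,
    simes_correct,
    standardize_grand,
    within_group_contrasts,
)
from esmstress.mlm import linear_contrast, within_recovery_deviation
from esmstress.pipeline import RunConfig, build_frame, prepare_derived
from conftest import small_config
from helpers import dense_ml_fit, dense_mvn_loglik


def _frame(n=10, seed=3, **cfg):
    ds, _ = generate(small_config(n, **cfg), seed=seed)
    filtered, _ = apply_compliance_filter(ds)
    derived = standardize_grand(derive_prompts(filtered))
    return build_frame(derived, "composite", 2)


def fake_fit(beta: dict, se: dict | None = None, spec: ModelSpec | None = None,
             time_levels=("t-1", "t0", "t1", "t2"),
             group_levels=("control", "at_risk", "patient")) -> FitResult:
    """FitResult with hand-set coefficients and a diagonal covariance."""
    idx = list(beta)
    b = pd.Series(beta, dtype=float)
    v = np.diag([se.get(k, 0.01) ** 2 if se else 0.01 ** 2 for k in idx])
    return FitResult(
        beta=b, vcov=pd.DataFrame(v, index=idx, columns=idx),
        var_person=0.3, var_day=0.1, var_resid=0.6, loglik=0.0, converged=True,
        n_obs=100, n_days=50, n_persons=10,
        time_levels=list(time_levels), group_levels=list(group_levels),
        spec=spec or ModelSpec(include_group_terms=True, include_interaction=True),
    )


class TestFitAgainstOracles:
    def test_zero_variance_components_reduce_to_ols(self):
        # homogeneous single group, truth var_person = var_day = 0: the ML
        # estimates land on the boundary and the GLS fit degenerates to OLS
        frame = _frame(10, seed=6, var_person=0.0, var_day=0.0, discretize=False)
        spec = ModelSpec(covariates=True, groups=("control",))
        fit = fit_lmm(frame, spec)
        assert fit.var_person < 1e-6 and fit.var_day < 1e-6
        from esmstress.mlm import build_design
        data, terms, _, _ = build_design(frame, spec)
        X = sm.add_constant(data[terms].to_numpy())
        ols = sm.OLS(data["pa_z"].to_numpy(), X).fit()
        assert np.allclose(fit.beta.to_numpy(), ols.params, atol=1e-6)

    def test_loglik_matches_dense_mvn_evaluation(self):
        frame = _frame(4, seed=9)
        spec = ModelSpec(covariates=False)
        fit = fit_lmm(frame, spec)
        assert fit.converged
        from esmstress.mlm import build_design
        data, terms, _, _ = build_design(frame, spec)
        assert len(data) <= 200
        ll = dense_mvn_loglik(data, fit.beta, terms,
                              fit.var_person, fit.var_day, fit.var_resid)
        assert fit.loglik == pytest.approx(ll, abs=1e-6)

    def test_small_balanced_fit_matches_direct_ml(self):
        # 2 persons x 2 days x 2 obs, deterministic values
        data = pd.DataFrame({
            "person_id": ["a"] * 4 + ["b"] * 4,
            "day_index": [1, 1, 2, 2] * 2,
            "beep_index": list(range(2, 10)),
            "group": ["control"] * 8,
            "time_since": ["t-1", "t0"] * 4,
            "included": True,
            "pa_z": [0.0, 0.2, 0.4, 0.1, 1.0, 1.4, 0.8, 1.1],
            "age": 30.0, "gender": "female",
        })
        spec = ModelSpec(covariates=False)
        fit = fit_lmm(data, spec)
        oracle_data = data.assign(ts_t0=(data["time_since"] == "t0").astype(float))
        oracle = dense_ml_fit(oracle_data, ["ts_t0"])
        assert fit.loglik == pytest.approx(oracle["loglik"], abs=1e-5)
        assert fit.beta["Intercept"] == pytest.approx(oracle["beta"][0], abs=1e-4)
        assert fit.beta["ts_t0"] == pytest.approx(oracle["beta"][1], abs=1e-4)
        assert fit.var_person == pytest.approx(oracle["var_person"], abs=1e-3)

    def test_group_model_loglik_dominates_nested_model(self):
        frame = _frame(8, seed=13)
        ll0 = fit_lmm(frame, ModelSpec(covariates=False)).loglik
        ll1 = fit_lmm(frame, ModelSpec(covariates=False,
                                       include_group_terms=True)).loglik
        assert ll1 >= ll0 - 1e-6

    def test_single_fit_recovers_reactivity_roughly(self):
        ds, truth = generate(small_config(40, discretize=False), seed=21)
        filtered, _ = apply_compliance_filter(ds)
        frame = build_frame(standardize_grand(derive_prompts(filtered)), "composite", 2)
        fit = fit_lmm(frame, ModelSpec(groups=("control",)))
        c = within_group_contrasts(fit, ["t0"])[0]
        assert abs(c.b - truth.reactivity["control"]) < 4 * c.se


class TestContrasts:
    def test_ci_formatting_template(self):
        fit = fake_fit({"Intercept": 0.1, "ts_t0": -0.38}, se={"ts_t0": 0.0357},
                       spec=ModelSpec())
        c = within_group_contrasts(fit, ["t0"])[0]
        assert round(c.ci_low, 2) == -0.45
        assert round(c.ci_high, 2) == -0.31
        assert c.p < 0.001

    def test_absent_timepoint_gives_labeled_gap(self):
        fit = fake_fit({"Intercept": 0.0, "ts_t0": -0.3}, spec=ModelSpec())
        c = within_group_contrasts(fit, ["t2"])[0]
        assert np.isnan(c.b) and "absent" in c.note

    def test_contrast_equals_margin_difference(self):
        frame = _frame(10, seed=17)
        fit = fit_lmm(frame, ModelSpec(include_group_terms=True,
                                       include_interaction=True))
        assert fit.converged
        margins = adjusted_margins(fit).set_index(["group", "time_since"])
        c = within_group_contrasts(fit, ["t0"])[0]  # reference group t0 vs t-1
        gap = margins.loc[("control", "t0"), "margin"] - margins.loc[("control", "t-1"), "margin"]
        assert c.b == pytest.approx(gap, abs=1e-10)

    def test_margin_at_reference_equals_intercept_contribution(self):
        frame = _frame(10, seed=17)
        fit = fit_lmm(frame, ModelSpec(include_group_terms=True,
                                       include_interaction=True))
        m = adjusted_margins(fit, female_at=0.5).set_index(["group", "time_since"])
        expect = fit.beta["Intercept"] + 0.5 * fit.beta["female"]
        assert m.loc[("control", "t-1"), "margin"] == pytest.approx(expect, abs=1e-10)

    def test_pairwise_difference_identity(self):
        frame = _frame(10, seed=19)
        fit = fit_lmm(frame, ModelSpec(include_group_terms=True,
                                       include_interaction=True))
        cons = {c.label: c for c in between_group_contrasts(fit, "t-1")}
        lhs = cons["patient vs at_risk at t-1"].b
        rhs = (cons["patient vs control at t-1"].b
               - cons["at_risk vs control at t-1"].b)
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_nonconverged_fit_propagates_marker(self):
        fit = dataclasses.replace(
            fake_fit({"Intercept": 0.0, "g_patient": 0.1}), converged=False)
        cons = between_group_contrasts(fit, "t-1")
        assert all("converge" in c.note for c in cons)
        assert all(np.isnan(c.b) for c in cons)


class TestGroupMainEffect:
    def test_one_df_identity(self):
        frame = _frame(10, seed=23)
        frame = frame[frame["group"] != "at_risk"]
        fit = fit_lmm(frame, ModelSpec(include_group_terms=True))
        ge = group_main_effect(fit)
        c = linear_contrast(fit, {"g_patient": 1.0}, "patient gap")
        assert ge["df"] == 1
        assert ge["chi2"] == pytest.approx((c.b / c.se) ** 2, abs=1e-10)

    def test_df_two_with_three_groups(self):
        frame = _frame(8, seed=23)
        ge = group_main_effect(fit_lmm(frame, ModelSpec(include_group_terms=True)))
        assert ge["df"] == 2

    def test_requires_group_terms(self):
        with pytest.raises(ValueError):
            group_main_effect(fake_fit({"Intercept": 0.0}, spec=ModelSpec()))


def _c(label, p, b=-0.1):
    return Contrast(label, b, b - 0.05, b + 0.05, p)


class TestRecovery:
    def test_window_from_p_sequences(self):
        within = {
            "patient": [_c("t1", 0.02), _c("t2", 0.71)],
            "at_risk": [_c("t1", 0.03), _c("t2", 0.23)],
            "control": [_c("t1", 0.32), _c("t2", 0.25)],
        }
        win = recovery_window(within)
        assert win["per_group"] == {"patient": 2, "at_risk": 2, "control": 1}
        assert win["window"] == [1, 2]

    def test_all_recovered_at_t1_gives_single_point_window(self):
        within = {g: [_c("t1", 0.5), _c("t2", 0.8)] for g in ("a", "b")}
        assert recovery_window(within)["window"] == [1]

    def test_no_recovery_within_horizon_caps_window(self):
        within = {"a": [_c("t1", 0.001), _c("t2", 0.001)]}
        win = recovery_window(within)
        assert win["per_group"]["a"] == 3
        assert win["window"] == [1, 2]

    def test_within_group_average_deviation_arithmetic(self):
        fit = fake_fit({"Intercept": 0.0, "ts_t0": -0.3, "ts_t1": -0.12,
                        "ts_t2": -0.02}, spec=ModelSpec())
        c = within_recovery_deviation(fit, [1, 2], "control")
        assert c.b == pytest.approx(-0.07)

    def test_between_group_recovery_linearity_identity(self):
        frame = _frame(10, seed=29)
        fit = fit_lmm(frame, ModelSpec(include_group_terms=True,
                                       include_interaction=True))
        rc = recovery_contrast(fit, [1, 2], ("patient", "control"))
        singles = [between_group_contrasts(fit, f"t{k}") for k in (1, 2)]
        parts = [next(c for c in s if c.label.startswith("patient vs control"))
                 for s in singles]
        assert rc.b == pytest.approx(np.mean([p.b for p in parts]), abs=1e-10)

    def test_window_beyond_model_horizon_rejected(self):
        fit = fake_fit({"Intercept": 0.0, "ts_t0": -0.3, "ts_t1": -0.1},
                       time_levels=("t-1", "t0", "t1"), spec=ModelSpec(
                           include_group_terms=True, include_interaction=True))
        with pytest.raises(ValueError, match="beyond"):
            recovery_contrast(fit, [1, 2], ("patient", "control"))

    def test_identical_groups_give_near_zero_recovery_contrast(self):
        frame = _frame(15, seed=31, baseline_offset={g: 0.0 for g in
                       ("control", "at_risk", "patient")},
                       reactivity={g: -0.3 for g in ("control", "at_risk", "patient")},
                       recovery_lag={g: 2 for g in ("control", "at_risk", "patient")})
        fit = fit_lmm(frame, ModelSpec(include_group_terms=True,
                                       include_interaction=True))
        rc = recovery_contrast(fit, [1, 2], ("patient", "control"))
        assert abs(rc.b) < 4 * rc.se


class TestSimes:
    def test_stated_rule_application(self):
        out = simes_correct((0.001, 0.026, 0.2))
        assert out.significant == (True, False, False)
        assert out.thresholds_rounded == (0.02, 0.03, 0.05)

    def test_all_large_p_rejected_nothing(self):
        assert simes_correct((0.9, 0.9, 0.9)).significant == (False, False, False)

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            simes_correct((0.01, 0.02))
        with pytest.raises(ValueError):
            simes_correct((0.01, 0.02, 0.03, 0.04))

    @given(st.lists(st.floats(0.0001, 1.0), min_size=3, max_size=3),
           st.integers(0, 2), st.floats(0.1, 0.99))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_decreasing_a_p_value_never_unflags(self, ps, idx, shrink):
        before = simes_correct(ps).significant
        ps2 = list(ps)
        ps2[idx] = ps2[idx] * shrink
        after = simes_correct(ps2).significant
        for i in range(3):
            if i != idx and before[i]:
                assert after[i]
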