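"""Independent oracles used by unit and acceptance tests.

These deliberately re-derive quantities by the most literal route
possible (row scans, dense linear algebra) and share no code with the
implementation paths they check.
"""

import numpy as np
import pandas as pd


def brute_force_time_since(derived: pd.DataFrame, stress_type: str, max_lag: int):
    """Per-row (time_since, included, reason) by explicit per-day scanning."""
    col = f"{stress_type}_stress"
    out = {}
    ever = derived.groupby("person_id")[col].any()
    for (pid, day), rows in derived.groupby(["person_id", "day_index"]):
        rows = rows.sort_values("beep_index")
        keys = [(pid, day, b) for b in rows["beep_index"]]
        if not ever[pid]:
            for k in keys:
                out[k] = (None, False, "never_stressed")
            continue
        flags = list(rows[col].astype(bool))
        if True not in flags:
            for k in keys:
                out[k] = (None, False, "no_stress_day")
            continue
        pos = flags.index(True)
        if pos == 0:
            for k in keys:
                out[k] = (None, False, "first_prompt_stressor")
            continue
        for i, k in enumerate(keys):
            lag = i - pos
            if lag < -1:
                out[k] = (None, False, "pre_baseline")
            elif lag > max_lag:
                out[k] = (None, False, "beyond_window")
            else:
                lab = "t-1" if lag == -1 else f"t{lag}"
                out[k] = (lab, True, None)
    return out


def dense_mvn_loglik(data: pd.DataFrame, beta: pd.Series, terms: list[str],
                     var_person: float, var_day: float, var_resid: float) -> float:
    """Gaussian log-likelihood of the three-level random-intercept model,
    evaluated with an explicitly assembled marginal covariance matrix."""
    X = np.column_stack([np.ones(len(data))] + [data[t].to_numpy() for t in terms])
    b = beta.reindex(["Intercept"] + terms).to_numpy()
    resid = data["pa_z"].to_numpy() - X @ b

    person = pd.Categorical(data["person_id"])
    Zp = np.eye(len(person.categories))[person.codes]
    pd_key = data["person_id"].astype(str) + ":" + data["day_index"].astype(str)
    day = pd.Categorical(pd_key)
    Zd = np.eye(len(day.categories))[day.codes]

    V = (var_person * Zp @ Zp.T + var_day * Zd @ Zd.T
         + var_resid * np.eye(len(data)))
    sign, logdet = np.linalg.slogdet(V)
    assert sign > 0
    quad = resid @ np.linalg.solve(V, resid)
    n = len(data)
    return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)


def dense_ml_fit(data: pd.DataFrame, terms: list[str]):
    """Direct ML fit of the same model by generic optimization over
    log-variances with GLS-profiled fixed effects (small n only)."""
    from scipy.optimize import minimize

    X = np.column_stack([np.ones(len(data))] + [data[t].to_numpy() for t in terms])
    y = data["pa_z"].to_numpy()
    person = pd.Categorical(data["person_id"])
    Zp = np.eye(len(person.categories))[person.codes]
    pd_key = data["person_id"].astype(str) + ":" + data["day_index"].astype(str)
    day = pd.Categorical(pd_key)
    Zd = np.eye(len(day.categories))[day.codes]
    n = len(data)

    def neg_loglik(theta):
        vp, vd, ve = np.exp(theta)
        V = vp * Zp @ Zp.T + vd * Zd @ Zd.T + ve * np.eye(n)
        sign, logdet = np.linalg.slogdet(V)
        if sign <= 0:
            return 1e10
        Vi_X = np.linalg.solve(V, X)
        beta = np.linalg.solve(X.T @ Vi_X, Vi_X.T @ y)
        r = y - X @ beta
        return 0.5 * (n * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(V, r))

    best = None
    for start in ([0.0, 0.0, 0.0], [-2.0, -2.0, 0.0], [-6.0, -6.0, -1.0]):
        res = minimize(neg_loglik, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    vp, vd, ve = np.exp(best.x)
    V = vp * Zp @ Zp.T + vd * Zd @ Zd.T + ve * np.eye(n)
    Vi_X = np.linalg.solve(V, X)
    beta = np.linalg.solve(X.T @ Vi_X, Vi_X.T @ y)
    return {"beta": beta, "var_person": vp, "var_day": vd, "var_resid": ve,
            "loglik": -best.fun}
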