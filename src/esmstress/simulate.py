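"""Synthetic ESM data generator with exported ground truth.

Emulates the sampling design the pipeline expects — 10 pseudo-random
prompts/day in 90-minute blocks between 7:30 and 22:30 over 6 days,
three clinical-staging groups — with a latent affect process

    y = baseline_offset_g + u_i + v_id
        + reactivity_g * 1[first stressor of the day]
        + deficit_g,k  * 1[k-th post-stressor prompt, k < recovery_lag_g]
        + beta_age * age_c + beta_gender * female + eps

(u person intercept, v day-within-person intercept, eps residual), a
per-prompt Bernoulli stress process with correlated event/activity
types, and a compliance (missingness) process. Item responses (three PA
items, event pleasantness, four activity items) are emitted consistently
with the drawn stress indicators, so the scoring pipeline reconstructs
the flags exactly.

Two deliberate alignments make the exported ground truth the estimand of
the analysis pipeline: effects are planted along *answered* prompts
(stress is only observable when a prompt is answered, and trajectory
coding indexes answered occasions), and the day's first *composite*
stressor anchors the dip (the composite analysis is the
parameter-recovery reference; the single-type analyses see a noisier
version, as in real data). recovery_lag_g is the first post-stressor
prompt at which affect is back at baseline: deficits are planted for
lags k < recovery_lag_g, decaying geometrically from the reactivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data import ESMDataset, REQUIRED_COLUMNS

GROUPS = ("control", "at_risk", "patient")


def _default(d):
    return field(default_factory=lambda: dict(d))


@dataclass
class SimConfig:
    n_per_group: dict = _default({"control": 100, "at_risk": 100, "patient": 100})
    days: int = 6
    beeps_per_day: int = 10
    block_minutes: int = 90
    day_start: str = "07:30"

    baseline_offset: dict = _default({"control": 0.0, "at_risk": -0.28, "patient": -0.44})
    reactivity: dict = _default({"control": -0.32, "at_risk": -0.38, "patient": -0.38})
    recovery_lag: dict = _default({"control": 1, "at_risk": 2, "patient": 2})
    recovery_decay: float = 0.3
    recovery_deficit: dict | None = None    # {group: {lag: value}}, else geometric

    p_event: float = 0.22
    p_activity: float = 0.12
    overlap_odds_ratio: float = 2.0

    var_person: float = 0.30
    var_day: float = 0.08
    var_resid: float = 0.56

    compliance_prob: float = 0.78
    delay_max: float = 16.0
    timely_delay: float = 15.0   # the design's response-window rule

    age_mean: dict = _default({"control": 35.5, "at_risk": 36.4, "patient": 38.1})
    age_sd: dict = _default({"control": 12.6, "at_risk": 13.1, "patient": 11.4})
    female_prob: dict = _default({"control": 0.59, "at_risk": 0.585, "patient": 0.49})
    beta_age: float = 0.008
    beta_gender: float = -0.05

    discretize: bool = True
    item_noise_sd: float = 0.7
    pa_scale_mid: float = 4.3
    pa_scale_slope: float = 0.75

    seed: int = 12345

    def validate(self) -> None:
        probs = [self.p_event, self.p_activity, self.compliance_prob,
                 *self.female_prob.values()]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if min(self.var_person, self.var_day, self.var_resid) < 0:
            raise ValueError("variance components must be nonnegative")
        if self.days * self.beeps_per_day < 4:
            raise ValueError("need at least 4 prompts in the design")
        if any(l > self.beeps_per_day - 2 for l in self.recovery_lag.values()):
            raise ValueError("recovery_lag must be at most beeps_per_day - 2")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be nonnegative")

    def deficits(self) -> dict:
        """Planted deficit per group and lag (empty dict = recovered at t1)."""
        if self.recovery_deficit is not None:
            return {g: dict(v) for g, v in self.recovery_deficit.items()}
        out = {}
        for g in GROUPS:
            lag = self.recovery_lag.get(g, 1)
            out[g] = {
                k: self.reactivity[g] * self.recovery_decay ** k
                for k in range(1, lag)
            }
        return out


@dataclass
class GroundTruth:
    baseline_offset: dict
    reactivity: dict
    recovery_deficit: dict
    recovery_lag: dict
    var_person: float
    var_day: float
    var_resid: float
    beta_age: float
    beta_gender: float

    def as_dict(self) -> dict:
        return asdict(self)


def _activity_given_event(p_event, p_activity, odds_ratio):
    """Conditional activity-stress probabilities (given event / no event)
    with the requested marginal and odds ratio."""
    if p_activity in (0.0, 1.0) or p_event in (0.0, 1.0) or odds_ratio == 1.0:
        return p_activity, p_activity

    def gap(p0):
        o0 = p0 / (1 - p0)
        p1 = odds_ratio * o0 / (1 + odds_ratio * o0)
        return p_event * p1 + (1 - p_event) * p0 - p_activity

    lo, hi = 1e-9, min(1 - 1e-9, p_activity / (1 - p_event))
    p0 = brentq(gap, lo, hi)
    o0 = p0 / (1 - p0)
    p1 = odds_ratio * o0 / (1 + odds_ratio * o0)
    return p1, p0


def _fmt_time(minutes: np.ndarray, start: str) -> np.ndarray:
    h0, m0 = map(int, start.split(":"))
    total = h0 * 60 + m0 + minutes
    return np.char.add(
        np.char.zfill((total // 60).astype(int).astype(str), 2),
        np.char.add(":", np.char.zfill((total % 60).astype(int).astype(str), 2)),
    )


def generate(config: SimConfig | None = None, seed: int | None = None):
    """Simulate one dataset; deterministic under (config, seed).

    Returns ``(ESMDataset, GroundTruth)``. ``seed`` overrides
    ``config.seed`` when given.
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    groups = [g for g in GROUPS for _ in range(cfg.n_per_group.get(g, 0))]
    n = len(groups)
    if n == 0:
        raise ValueError("empty design: all group sizes are zero")
    pid = np.array([f"p{i:04d}" for i in range(n)])
    garr = np.array(groups)

    age = np.empty(n)
    female = np.empty(n, dtype=bool)
    for g in GROUPS:
        m = garr == g
        age[m] = np.clip(rng.normal(cfg.age_mean[g], cfg.age_sd[g], m.sum()), 18, 85)
    age = np.round(age, 1)
    for g in GROUPS:
        m = garr == g
        female[m] = rng.random(m.sum()) < cfg.female_prob[g]
    age_c = age - np.mean([cfg.age_mean[g] for g in GROUPS])

    D, B = cfg.days, cfg.beeps_per_day
    N = n * D * B
    person_ix = np.repeat(np.arange(n), D * B)
    day_ix = np.tile(np.repeat(np.arange(1, D + 1), B), n)
    beep_ix = np.tile(np.arange(1, B + 1), n * D)

    minutes = (beep_ix - 1) * cfg.block_minutes + rng.integers(0, cfg.block_minutes, N)
    sched = _fmt_time(minutes, cfg.day_start)

    answered = rng.random(N) < cfg.compliance_prob
    delay = np.where(answered, np.round(rng.uniform(0, cfg.delay_max, N), 1), np.nan)

    # stress process at answered prompts
    event = np.zeros(N, dtype=bool)
    activity = np.zeros(N, dtype=bool)
    event[answered] = rng.random(answered.sum()) < cfg.p_event
    p1, p0 = _activity_given_event(cfg.p_event, cfg.p_activity, cfg.overlap_odds_ratio)
    u = rng.random(answered.sum())
    activity[answered] = np.where(event[answered], u < p1, u < p0)
    composite = event | activity

    # Effects are planted along *valid* occasions (answered within the
    # design's response window): these are the measurement occasions the
    # analysis sequences, so the planted dip pattern is the estimand.
    valid = answered & (delay <= cfg.timely_delay)
    df = pd.DataFrame({"person": person_ix, "day": day_ix, "answered": valid,
                       "stress": composite & valid})
    apos = df[df["answered"]].groupby(["person", "day"]).cumcount()
    pos = pd.Series(np.nan, index=df.index)
    pos[df["answered"]] = apos
    stress_pos = pos.where(df["stress"] & df["answered"])
    first_pos = stress_pos.groupby([df["person"], df["day"]]).transform("min")
    lag = (pos - first_pos).to_numpy()  # NaN where no stressor / unanswered

    deficits = cfg.deficits()
    offs = np.array([cfg.baseline_offset[g] for g in garr])[person_ix]
    react = np.array([cfg.reactivity[g] for g in garr])[person_ix]
    dip = np.zeros(N)
    with np.errstate(invalid="ignore"):
        at_t0 = lag == 0
    dip[at_t0] = react[at_t0]
    for g in GROUPS:
        for k, val in deficits[g].items():
            m = (garr[person_ix] == g) & (lag == k)
            dip[m] = val

    u_i = rng.normal(0, np.sqrt(cfg.var_person), n)
    v_id = rng.normal(0, np.sqrt(cfg.var_day), n * D)
    day_flat = person_ix * D + (day_ix - 1)
    y = (offs + u_i[person_ix] + v_id[day_flat] + dip
         + cfg.beta_age * age_c[person_ix]
         + cfg.beta_gender * female[person_ix].astype(float)
         + rng.normal(0, np.sqrt(cfg.var_resid), N))

    # --- item emission ------------------------------------------------
    latent_pa = cfg.pa_scale_mid + cfg.pa_scale_slope * y
    pa_items = np.empty((N, 3))
    for j in range(3):
        if cfg.discretize:
            pa_items[:, j] = np.clip(
                np.round(latent_pa + rng.normal(0, cfg.item_noise_sd, N)), 1, 7)
        else:
            pa_items[:, j] = np.clip(latent_pa, 1, 7)

    ev_pleas = np.empty(N)
    ne, ns = int((~event).sum()), int(event.sum())
    ev_pleas[~event] = rng.choice([0, 1, 2, 3], ne, p=[0.2, 0.35, 0.3, 0.15])
    ev_pleas[event] = rng.choice([-1, -2, -3], ns, p=[0.5, 0.35, 0.15])

    # activity items on the *scored* scale (skilled reverse-coded back on emit)
    level = np.where(activity, rng.uniform(4.6, 6.0, N), rng.uniform(2.0, 3.8, N))
    act = np.clip(np.round(level[:, None] + rng.normal(0, 0.8, (N, 4))), 1, 7)
    score = act.mean(axis=1)
    mismatch = (score > 4) != activity
    act[mismatch] = 8 - act[mismatch]           # reflect around the midpoint
    score = act.mean(axis=1)
    tie = score == 4                             # still ambiguous: nudge one item
    bump = np.where(activity, 1, -1)
    pick = np.where(activity[tie], act[tie].argmin(axis=1), act[tie].argmax(axis=1))
    act[np.flatnonzero(tie), pick] += bump[tie]

    prompts = pd.DataFrame({
        "person_id": pid[person_ix],
        "group": garr[person_ix],
        "age": age[person_ix],
        "gender": np.where(female[person_ix], "female", "male"),
        "day_index": day_ix,
        "beep_index": beep_ix,
        "scheduled_time": sched,
        "response_delay_min": delay,
        "pa_cheerful": pa_items[:, 0],
        "pa_relaxed": pa_items[:, 1],
        "pa_satisfied": pa_items[:, 2],
        "event_pleasantness": ev_pleas,
        "act_energy": act[:, 0],
        "act_skilled": 8 - act[:, 1],
        "act_challenge": act[:, 2],
        "act_prefer_else": act[:, 3],
    })
    item_cols = REQUIRED_COLUMNS[8:]
    prompts.loc[~answered, item_cols] = np.nan

    persons = pd.DataFrame({"person_id": pid, "group": garr, "age": age,
                            "gender": np.where(female, "female", "male")})
    ds = ESMDataset(
        persons=persons, prompts=prompts,
        provenance={"n_days": D, "n_beeps_per_day": B, "source": "simulated",
                    "seed": int(cfg.seed if seed is None else seed)},
    )
    truth = GroundTruth(
        baseline_offset=dict(cfg.baseline_offset),
        reactivity=dict(cfg.reactivity),
        recovery_deficit=deficits,
        recovery_lag=dict(cfg.recovery_lag),
        var_person=cfg.var_person, var_day=cfg.var_day, var_resid=cfg.var_resid,
        beta_age=cfg.beta_age, beta_gender=cfg.beta_gender,
    )
    return ds, truth


def scenario_library() -> dict:
    """Named presets covering the validation scenarios.

    - ``paper-like``: three staging groups with baseline offsets
      0 / −0.28 / −0.44 (control / at-risk / patient), reactivity
      −0.32 / −0.38 / −0.38 and recovery at t1 / t2 / t2; continuous PA
      emission so planted effects live on the analysis scale.
    - ``null``: identical groups, no planted effects (type-I calibration).
    - ``no-random-effects``: person and day variances zero.
    - ``high-missingness``: compliance 0.5.
    """
    zero = {g: 0.0 for g in GROUPS}
    return {
        "paper-like": SimConfig(discretize=False),
        "null": SimConfig(
            baseline_offset=dict(zero), reactivity=dict(zero),
            recovery_lag={g: 1 for g in GROUPS},
            beta_age=0.0, beta_gender=0.0,
        ),
        "no-random-effects": SimConfig(var_person=0.0, var_day=0.0),
        "high-missingness": SimConfig(compliance_prob=0.5),
    }


def get_scenario(name: str, **overrides) -> SimConfig:
    lib = scenario_library()
    if name not in lib:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(lib)}")
    cfg = lib[name]
    return replace(cfg, **overrides) if overrides else cfg
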