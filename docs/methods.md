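# Methods

## The scientific setting

Experience sampling (ESM / ecological momentary assessment) collects
brief in-the-moment self-reports many times a day. The design emulated
here signals participants 10 times per day at pseudo-random moments
inside consecutive 90-minute blocks between 07:30 and 22:30, for 6
days. Three clinical-staging groups are compared — patients with a
mental disorder, individuals at familial or psychometric risk, and
controls — on three momentary quantities:

- **positive affect (PA)**: mean of the items *cheerful*, *relaxed*,
  *satisfied* (each 1–7);
- **event-related stress**: the pleasantness of the most important
  recent event, rated on a bipolar −3..+3 scale and recoded to 1–7
  unpleasantness (`u = 4 − x`); an event is counted as a stressor when
  the recoded score exceeds the scale midpoint, i.e. the original
  rating was negative;
- **activity-related stress**: mean of four appraisal items about the
  current activity (*costs energy*, *skilled at this* reverse-coded,
  *a challenge*, *prefer doing something else*), a stressor when the
  mean exceeds the midpoint 4;
- **composite stress**: presence of either type (logical OR).

The dichotomization thresholds are not canonical in the literature;
both are exposed in the configuration (`event_threshold`,
`activity_threshold`, strict `>`, defaults 4 and 4). A score with fewer
than 2 of 3 PA items (or 2 of 4 activity items) answered is missing —
a conventional EMA completeness rule.

Descriptive tables report the unpleasantness of each day's first
stressor on two candidate scales — the recoded 1–7 unpleasantness and
the absolute bipolar rating (1–3) — because published cohort tables are
ambiguous about which scale such summaries use (means near 2 are only
arithmetically possible on the 1–3 reading).

## Compliance rules

Only prompts answered within 15 minutes of the signal count, prompts
with every PA and stress item missing are dropped with them, and
persons retaining fewer than 20 prompts are removed entirely. The two
stages are logged separately so the accounting (input = retained +
removed) is auditable at every step. Compliance percentages are
reported as half-up-rounded integers (47/60 → 78%).

## Trajectory coding

For each stress measure, the first flagged prompt of a person-day
becomes **t0** (reactivity); the answered prompt immediately before it
is the baseline **t−1**; following answered prompts are **t1..tK**.
Days without a stressor, days whose first answered prompt is already
stressful (no baseline observable), and persons who never report the
measure are excluded, as are prompts before t−1 and beyond tK.
Occasions are indexed over *answered* prompts: a missed beep shifts the
labels to the next answered prompt, which keeps adjacent labels roughly
90 minutes apart in expectation and matches how the model treats
measurement occasions. The follow-up horizon K defaults to 1 prompt for
event stress and 2 for activity and composite stress (the windows over
which recovery is observable in this design); prompts beyond tK are
excluded rather than pooled so the baseline contrast stays
interpretable.

## Outcome scaling

The analysis outcome `pa_z` is grand-standardized PA: `(pa_raw − mean) /
SD` over all analyzed prompts, a pure location–scale change. Person and
day means are *not* subtracted from the outcome; the three-level random
intercepts absorb them. This choice is deliberate: subtracting each
person's own mean would remove every between-person — hence every
between-group — level difference, making the baseline staging contrasts
(the H2 quantities) identically zero by construction, and subtracting
day means would bias the within-day reactivity contrast by the day's
mean stress dip. A doubly-demeaning transform
(`center_and_standardize`, person means then person-day means, then one
global SD) is provided for analyses of pure within-person fluctuation
and is selectable via `RunConfig(centering="person_day")`; the pipeline
default is `"grand"`.

## The model

For each stress measure,

    pa_z ~ time_since (+ group + time_since×group) (+ age_c + female)
           (+ subsequent_stress)

with random intercepts for person (level 3) and day-within-person
(level 2), fitted by maximum likelihood (REML is a config option) via
`statsmodels` MixedLM. t−1 is the reference time category and controls
the reference group. Age is centered at the grand mean of the analytic
sample of that model; gender enters as a female indicator. Inference is
large-sample Wald throughout: 95% CIs use ±1.96·SE and p-values the z
statistic, matching mixed-model software that reports z/chi-square
tests; no Satterthwaite or Kenward–Roger correction is applied. If an
optimizer fails, slower fallbacks are tried; a model that still does
not converge is reported as such and its contrasts propagate a
non-convergence marker — never silently replaced by a simpler model.

The hypothesis sequence:

1. **H1 (within-group)**: separate per-group models; each t0..tK
   coefficient is the deviation from baseline.
2. **H2 (levels)**: group added as a predictor; the joint Wald
   chi-square over the group dummies is the group main effect, and the
   dummy contrasts are the baseline gaps.
3. **H3 (reactivity)**: time_since × group interaction; the t0
   interaction contrasts compare reactivity between groups. The
   between-group "t0" rows of the output tables are these interaction
   contrasts (differences in deviation from baseline), not absolute
   level gaps; `level_difference=True` gives the latter.
4. **H4 (recovery)**: per group, the recovery point L_g is the first
   follow-up prompt whose deviation from baseline is no longer
   significant at α; the common recovery window runs t1..t_max(L_g).
   The recovery quantity is the *average* deviation from baseline over
   that window, and the between-group contrast is the difference of
   those averages (an average of interaction coefficients, Wald via the
   delta method — linear, so exact).
5. **Sensitivity**: the same models with a binary covariate marking the
   presence of the same stress type at each follow-up prompt
   (structurally zero at t−1/t0).

Multiplicity across the three stress measures uses the Simes step rule:
within each hypothesis family the smallest of the three p-values is
compared with α/3, the middle with α/2, the largest with α. Where a
family has only two members (event stress has no recovery window) the
same rule applies with m=2. Pairwise contrasts within one model are not
corrected against each other.

## Synthetic data generator

The generator emulates the design above with a latent affect process

    y = offset_g + u_i + v_id + reactivity_g·1[t0]
        + deficit_g,k·1[k-th post-stressor prompt, k < lag_g]
        + β_age·age_c + β_gender·female + ε

with `u ~ N(0, σ²_person)`, `v ~ N(0, σ²_day)`, `ε ~ N(0, σ²_resid)`.
Default effect sizes plant the qualitative staging structure: baseline
offsets 0 / −0.28 / −0.44 (control / at-risk / patient), reactivity
−0.32 / −0.38 / −0.38, recovery at the 1st / 2nd / 2nd post-stressor
prompt. Recovery deficits decay geometrically from the reactivity with
factor 0.3 per lag (so the planted t1 deficit is ≈ 0.3× the t0 dip,
matching the empirical t1/t0 ratio of such trajectories); `recovery_lag`
is the first post-stressor prompt at which affect is *back at* baseline,
so controls carry no planted deficit. Variance components default to
σ²_person = 0.30, σ²_day = 0.08, σ²_resid = 0.56 — intraclass
correlations typical of EMA affect data — chosen so the total latent
variance including the fixed-effect contribution is ≈ 1 and planted
effects are already approximately on the z scale of the analyzed
outcome (residual scale error ≈ 1%).

Stress indicators are Bernoulli per prompt (event .22, activity .12)
with an odds-ratio-2 overlap so the composite measure is non-trivial;
nearly every person-day then carries a composite stressor, as in dense
EMA stress data. Item responses are emitted consistently with the drawn
indicators (stressed events draw from the unpleasant side of the
bipolar scale, stressed activities above the appraisal midpoint), so
the scoring pipeline reconstructs the flags exactly. The compliance
process answers each prompt with probability .78 and draws delays
uniformly on [0, 16] minutes, so ~6% of answered prompts violate the
15-minute rule and exercise the filter.

Two alignment choices make the exported ground truth the exact estimand
of the pipeline: effects are planted along answered-and-timely prompts
(the occasions the trajectory coder sequences), and the day's first
*composite* stressor anchors the dip — the composite analysis is the
parameter-recovery reference, while the single-type analyses see the
kind of misalignment real data would produce. By default PA items are
discretized (latent → 1–7 with item noise and rounding); the
`paper-like` preset emits continuous items instead, because grand
z-standardization is equivariant under the linear latent→item map
while rounding/clipping adds a few percent attenuation that is not part
of the planted truth.

What the generator does **not** emulate: autocorrelated residuals,
time-of-day and day-of-week affect cycles, informative missingness
(compliance is independent of affect and stress), graded stress
intensity, floor/ceiling response styles, and any correlation between
stress exposure and the random effects. Passing parameter-recovery
tests therefore shows the estimator is correct under the stated model,
not that the model is adequate for any particular real dataset.

## Monte-Carlo validation and problem sizes

The test suite validates the pipeline at these scales (chosen to keep
the default suite run in the tens of minutes on one CPU):

- parameter recovery: 200 replicates at 100 persons/group; mean
  estimated baseline gaps, per-group reactivity, and the t1–t2 recovery
  contrast are required to sit within the Monte-Carlo CI of the planted
  truth, and 95% CI coverage within [0.92, 0.98]. A 200-replicate run
  during development gave means within ~1 MC SE of truth on all six
  quantities and coverages 0.955–0.96.
- null calibration: 400 replicates with identical groups at 60 persons;
- qualitative recovery ordering: 30 replicates at 150 persons/group.

## Known limitations

- **Small-sample Wald inflation.** With 60 persons the group
  main-effect Wald chi-square (a between-person test with ~56 effective
  df and 4 between-person parameters) rejects a true null in ≈ 8% of
  replicates at nominal 5% (0.079 over 1000 replicates) — with ML *and*
  REML. This is the familiar
  anti-conservativeness of large-sample reference distributions for
  between-cluster effects in moderate samples, not an implementation
  defect (the likelihood matches a dense multivariate-normal evaluation
  to 1e-6); the same test is calibrated at larger samples (0.047 over
  300 replicates with 180 persons). Users comparing small groups should prefer more
  persons or a df-corrected test from other software.
- **The recovery ordering is a low-power pattern.** The planted t1
  deficit (0.3 × reactivity ≈ 0.11 z units) is detected with only
  ~50–80% power per group at 150 persons/group, and declaring a group
  "recovered" is itself a ~.95-probability event under the true null,
  so the full ordering (controls at t1, both clinical groups at t2)
  reproduces in well under 90% of replicates — its joint probability is
  bounded by .95³ ≈ .86 even with perfect power at any sample size. The
  pipeline reports per-group recovery points honestly; the pattern
  should be read descriptively, not as a reliable test outcome.
- Stress is dichotomous by design; graded intensity modeling is out of
  scope.
- Wald CIs and z p-values throughout; no Bayesian or autocorrelated
  residual options.
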