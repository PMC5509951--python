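# Methods

## The index

Each participant is observed from registration to the day her infant turns
39 weeks. The window is cut into three infant-age periods — [0, 13), [13,
26) and [26, 39) weeks — with half-open boundaries (an event at exactly 13
weeks belongs to the interim period). Events before birth are possible
(expectant parents may enrol from 30 weeks gestation) and are assigned to
period 1; no antenatal period exists, and the periods are infant-age-based,
so this is the only consistent choice. Calendar arithmetic is in days on
naive timestamps; weeks are real numbers (no time zones — app exports in
this setting are single-country).

Per period j the four usage subindices are:

| component | definition | empty-period value |
|---|---|---|
| click depth C_ij | (sessions with pages ≥ threshold) / sessions | 0 |
| loyalty L_ij | 1 − 1/s ("wad" convention) or 1/s ("literal") | 0 |
| interaction I_ij | pushes opened / pushes sent | 0 |
| recency R_i1 | 1 / (days from registration to first session) | 0 |
| recency R_i2, R_i3 | 1 / (mean gap in days between in-period sessions) | 0 |

Each overall subindex is the plain mean of its three period components. A
period with no qualifying activity contributes 0 and is never dropped:
non-use is zero engagement, so early quitters score lower — the behaviour a
longitudinal engagement measure should have. Zero-day activation and
sub-day mean gaps cap the reciprocal at 1.0 to preserve the [0, 1] range.
Recency gaps are computed within a period only; a lone session in a period
yields 0 (a single return visit tells nothing about rhythm).

The loyalty prose convention ("reciprocal of the number of sessions")
*decreases* with use; the default here is the cited web-analytics
construction 1 − 1/s, which increases with use and matches how the loyalty
subindex is reported to track engagement. The literal reading remains
available (`loyalty_convention="literal"`) for sensitivity analysis.

The feedback subindex dichotomizes each of 37 Likert items to 1 only at
the extreme positive response (reverse-worded items: "strongly disagree";
the push-receipt item: either delivery channel counts; "didn't use" and
unanswered score 0). The shipped `DEFAULT_SCORING_KEY` lists the 37 items
in questionnaire order with their polarities (7 reverse-worded, 1 receipt).
Three feedback cases exist:

- completed survey → F_i = (item score sum)/37;
- survey not completed → F_i = 0, EI still averages five subindices
  (numerically identical to averaging in a zero, but the count matters for
  the metadata);
- participant reported using the website instead of the app (never asked
  the feedback items) → F_i is *unavailable* and the EI averages the four
  usage subindices.

EI = 100 × mean(available subindices). Cohort cut-points are the EI
quartiles under linear interpolation between order statistics (the numpy
default; `run_metadata.json` records the rule for every run).
Categories: poor (EI ≤ Q1), high (EI ≥ Q3), moderate between; boundary
ties go outward so the extreme categories are closed sets.

## Determinant analysis

Fourteen candidate covariates (maternal age, education, employment,
income, marital status, parity, recruitment route, device, delivery
system, country of birth, infant birth weight, infant sex, baseline
feeding mode, infant age at registration) are first mapped from raw
questionnaire labels to analysis categories (`dichotomize`; the mapping is
idempotent, unmapped labels are flagged missing and logged, unlisted
countries collapse to "other", and the income "no response" option is a
retained level, not missingness).

Screening tests each covariate against the EI: correlation for continuous
covariates, two-sample location tests for binary ones, one-way comparisons
for ≥ 3 levels. Both branches are always computed and reported — Pearson /
t / ANOVA and Spearman / Mann-Whitney / Kruskal-Wallis — and the reported
`test_used` is chosen by Shapiro-Wilk normality checks at α = .05 (on both
variables for correlations; on each group of size ≥ 3 for comparisons), so
the choice is auditable rather than silent. Covariates with *P* ≤ .25
enter the full OLS model (dummy coding, declared reference levels,
complete cases per model, rank-deficiency is fatal with the aliased terms
named). Multi-level factors are kept or dropped whole via joint F-tests.
The reduced model is backward elimination: repeatedly drop the covariate
with the largest joint p-value above .05 and refit. Output tables render
reference levels as B = 1.00, the convention of the field's regression
tables; internally the reference coefficient is 0.

Two honest caveats, measured with this package's own simulations:
backward elimination's per-variable null retention runs slightly above the
nominal 5% (variables can drift below the threshold as competitors leave
the model — stepwise selection is mildly anti-conservative); and infant
age at registration is structurally associated with the EI even when no
effect is injected, because registering near the 13-week eligibility limit
plus an activation delay can leave no period-1 scoring opportunity at all.
The second is a property of the index, not a bug: joining later really is
less engagement opportunity.

## The synthetic cohort generator

The generator emulates the structure the index assumes, for a default
cohort of 300 mother–infant dyads:

- **Latent propensity.** θ_i = expit(logit(Beta(2.2, 2.2)) + covariate
  shifts). One latent trait drives every channel, which is the regime in
  which a composite index is meaningful. Covariate effects are specified
  in EI points and divided by a fixed calibration constant (9.2 EI points
  per logit unit, measured once from the generator's θ→EI response) before
  entering the latent scale; each effect term is mean-centered so the
  marginal θ distribution does not drift with the effect configuration.
  Defaults: primiparous +6, both-app-and-email +8, practitioner-recruited
  +5, −0.9 per week of infant age at registration — moderate, reliably
  detectable determinants at n = 300.
- **Enrolment.** Infant age at registration ~ truncated normal, mean 6.9,
  SD 3.6 weeks on [−6, 13] (a clipped normal would pile an atom of
  registrations at exactly 13 weeks and wipe their period-1 scores
  deterministically). Activation delay ~ geometric with mean
  10·(1−θ)/θ days (cohort mean ≈ two weeks, long right tail).
- **Usage.** Per-period session counts ~ negative binomial with mean
  11·θ·d_j, decay d = (1.0, 0.55, 0.30) — the initial-burst-then-fade
  profile typical of mHealth programs; sessions are placed uniformly in
  the feasible part of the period (after activation), and a period that
  ends before activation has none. Pages per session = 1 + negative
  binomial whose mean (0.8 + 3.2·θ) also decays by period: early sessions
  are the deep ones. Dispersion parameters (5.0 sessions, 4.0 pages) set
  channel noise low enough that the EI tracks θ (Spearman ≈ 0.85) while
  still overdispersed relative to Poisson.
- **Messages.** Push notifications on a fixed 3-per-week schedule
  (days 0/2/4 of each week from activation until the window ends; a
  participant activating at birth receives exactly 3 × 39 = 117), opened
  independently with probability 0.32·θ·d_j. Weekly emails appear for
  "both app and email" participants from infant week 13, emulating the
  mid-program addition of an email channel; emails never enter the
  interaction subindex by default but can via
  `interaction_channels={"push", "email"}`.
- **Survey.** Completion probability expit(logit(0.66) + 2·logit θ) —
  engaged participants complete more; 5% of completers report website use;
  item-level extreme-positive responses are Bernoulli(0.4·θ²) per item,
  giving the strongly right-skewed feedback scores such programs report.

`GroundTruth` retains θ, the injected effects and a tercile stratum.
`null_cohort` zeroes every injected effect and is otherwise byte-identical
machinery — the null for false-positive studies.

What the generator does **not** emulate: real session-boundary ambiguity
(sessions arrive pre-segmented), within-participant novelty dynamics
beyond the period decay, item-level response correlation in the survey,
seasonal or weekday usage patterns, and any dependence between channels
beyond the shared θ. Passing recovery tests therefore demonstrates that
the pipeline recovers structure *of this kind*; it cannot certify
behaviour under messier real-world logs.

## Numerical and procedural choices

- Percentile rule: linear interpolation; recorded in run metadata.
- Degenerate inputs: zero denominators score 0 (no sessions, no sent
  pushes, undefined recency); constant outcomes give R² = 0 and zero
  slopes; fewer than four EI values cannot define quartiles (fatal).
- Validation: dirty rows (unknown enum values, non-positive page counts,
  orphan events) are dropped with per-reason counts in the read report;
  duplicate participant ids and missing files are fatal.
- Floats are written to CSV via `repr`, so write-then-read round-trips
  exactly (readers parse with Python `float`).
- Problem sizes for the validation studies: 50 mini-cohorts (n ≤ 20) for
  oracle equivalence, 100 default cohorts for gradient and effect
  retention, 500 effect-free cohorts for false-positive retention —
  enough replicates that the binomial bands on the reported rates are a
  few percentage points wide.

## Known limitations

- Between-period recency gaps (last session of period 2 to first of
  period 3) are ignored by construction; an alternative cross-boundary
  definition was not implemented.
- The EI of website users averages four subindices and is therefore not
  strictly comparable to five-subindex scores; the `n_subindices_used`
  column makes the distinction explicit.
- Backward elimination inherits the usual caveats of stepwise selection
  (slightly anti-conservative, unstable near the threshold); the full
  model is always reported alongside.
- Cut-points are cohort-relative; cross-cohort comparisons need the
  `cutpoints_override` mechanism and shared conventions.
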