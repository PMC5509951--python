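"""Synthetic cohort generator with retained ground truth.

Emulates the statistical structure the engagement index assumes, for a
feasibility-study-like cohort of ~300 mother-infant dyads followed from
registration (infant on average 6.9 weeks old) to infant age 39 weeks:

* a single latent engagement propensity theta in (0, 1) per participant
  drives every channel — activation delay, session counts, pages viewed,
  push-notification opens, survey completion and survey positivity — so the
  composite index is a meaningful summary of one underlying trait;
* covariate effects (specified in EI points, converted to latent logit
  shifts through a fixed calibration constant) shift theta, giving the
  determinant analysis something to recover;
* per-period activity decays (default multipliers 1.0 / 0.55 / 0.35),
  emulating the intense initial use and later drop-off typical of mHealth
  programs;
* push notifications follow a fixed 3-per-week schedule from activation to
  the end of the window; weekly emails appear for "both app and email"
  participants from infant age 13 weeks (emulating the mid-program addition
  of emails after push-notification delivery problems);
* the end-of-program survey is completed more often by engaged
  participants, and a small fraction report using the website instead of
  the app (these are never asked the feedback items).

Everything is deterministic given the seed. :class:`GroundTruth` retains
theta, the injected effects and a tercile stratum for recovery tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .data_model import ITEM_COLUMNS, CohortDataset
from .subindices import DEFAULT_SCORING_KEY, NEGATIVE, POSITIVE, RECEIPT

_DAY = pd.Timedelta(days=1)

#: EI points gained per unit shift of the latent logit propensity, measured
#: once from the generator's theta -> EI response under default settings and
#: frozen; covariate effect sizes below are stated in EI points and divided
#: by this constant before entering the latent scale.
EI_PER_LOGIT = 9.2

DEFAULT_PREVALENCES: Mapping[str, object] = {
    "parity_primiparous": 0.62,
    "education_degree": 0.50,
    "employment_not_in_labor_force": 0.84,
    "marital_relationship": 0.97,
    "income": {"no_response": 0.07, "below_average": 0.30, "average": 0.20,
               "above_average": 0.15, "higher_income": 0.28},
    "recruitment": {"practitioner": 0.48, "web_based": 0.32,
                    "family_or_friends": 0.20},
    "device_ios": 0.70,
    "system_both": 0.71,
    "infant_sex_male": 0.47,
    "baseline_feeding": {"breastfeeding": 0.56, "formula_feeding": 0.26,
                         "mixed_feeding": 0.18},
    "country_of_birth": {"australia": 0.78, "new_zealand": 0.06,
                         "united_kingdom": 0.06, "other": 0.10},
}

#: Injected covariate effects on the EI scale (points; continuous effects
#: are per unit of the centered covariate). Magnitudes emulate moderate,
#: detectable determinants of engagement in a cohort of ~300.
DEFAULT_EFFECTS: Mapping[str, float] = {
    "parity=primiparous": 6.0,
    "system=both_app_and_email": 8.0,
    "recruitment=practitioner": 5.0,
    "infant_age_at_T1_weeks": -0.9,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator (defaults = the emulated study)."""

    n_participants: int = 300
    seed: int = 0
    covariate_prevalences: Mapping[str, object] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS))
    period_decay: tuple[float, float, float] = (1.0, 0.55, 0.30)
    notifications_per_week: int = 3
    mean_infant_age_at_registration_weeks: float = 6.9
    sd_infant_age_at_registration_weeks: float = 3.6
    survey_completion_prob: float = 0.66
    survey_completion_slope: float = 2.0
    website_user_prob: float = 0.05
    session_rate: float = 11.0
    session_dispersion: float = 5.0
    pages_mean_base: float = 0.8
    pages_mean_slope: float = 3.2
    pages_dispersion: float = 4.0
    open_prob_scale: float = 0.32
    email_open_prob_scale: float = 0.5
    activation_delay_scale: float = 10.0
    email_from_infant_week: float = 13.0
    theta_shape: float = 2.2
    start_date: str = "2015-01-01"

    def validate(self) -> "SimulationConfig":
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name in ("survey_completion_prob", "website_user_prob",
                     "open_prob_scale", "email_open_prob_scale"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(d < 0 for d in self.period_decay):
            raise ValueError("period_decay values must be >= 0")
        for name in ("session_rate", "session_dispersion", "pages_dispersion",
                     "activation_delay_scale", "theta_shape"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.notifications_per_week < 1:
            raise ValueError("notifications_per_week must be >= 1")
        return self


@dataclass
class GroundTruth:
    """Latent state retained for recovery testing."""

    frame: pd.DataFrame  # participant_id, theta, stratum
    effect_sizes: dict[str, float]

    @property
    def theta(self) -> pd.Series:
        return self.frame.set_index("participant_id")["theta"]


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _choice(rng, probs: Mapping[str, float], n: int) -> np.ndarray:
    levels = list(probs)
    p = np.asarray([probs[k] for k in levels], dtype=float)
    return rng.choice(levels, size=n, p=p / p.sum())


def _negbin(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Overdispersed counts: NB with shape k, mean mu (mu = 0 -> 0)."""
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + np.maximum(mean, 0.0))
    return rng.negative_binomial(dispersion, p)


def _covariates(rng, cfg: SimulationConfig) -> pd.DataFrame:
    n = cfg.n_participants
    prev = cfg.covariate_prevalences

    def binary(key, yes, no):
        return np.where(rng.random(n) < prev[key], yes, no)

    frame = pd.DataFrame({
        "parity": binary("parity_primiparous", "primiparous", "multiparous"),
        "education": binary("education_degree", "degree", "no_university"),
        "employment": binary("employment_not_in_labor_force",
                             "not_in_labor_force", "working_or_studying"),
        "marital": binary("marital_relationship", "relationship", "single"),
        "income": _choice(rng, prev["income"], n),
        "recruitment": _choice(rng, prev["recruitment"], n),
        "device": binary("device_ios", "ios", "android"),
        "system": binary("system_both", "both_app_and_email", "app_only"),
        "infant_sex": binary("infant_sex_male", "male", "female"),
        "baseline_feeding": _choice(rng, prev["baseline_feeding"], n),
        "country_of_birth": _choice(rng, prev["country_of_birth"], n),
        "mother_age_years": np.round(
            np.clip(rng.normal(30.4, 4.4, n), 18.0, 45.0), 1),
        "infant_birth_weight_g": np.round(
            np.clip(rng.normal(3460.0, 590.0, n), 1500.0, 5500.0), 0),
    })
    return frame


def _latent_eta(rng, cfg: SimulationConfig, cov: pd.DataFrame,
                age_weeks: np.ndarray) -> np.ndarray:
    n = cfg.n_participants
    a = cfg.theta_shape
    eta = _logit(rng.beta(a, a, size=n))
    # every effect term is mean-centered so the marginal propensity
    # distribution does not drift with the effect configuration
    for key, effect_ei in cfg.effect_sizes.items():
        shift = effect_ei / EI_PER_LOGIT
        if "=" in key:
            col, level = key.split("=", 1)
            x = (cov[col].to_numpy() == level).astype(float)
        elif key == "infant_age_at_T1_weeks":
            x = np.asarray(age_weeks, dtype=float)
        else:
            x = cov[key].to_numpy(dtype=float)
        eta += shift * (x - float(np.mean(x)))
    return eta


def _push_schedule(rng, cfg, pid_arr, activation, window_end, dob, theta):
    """3-per-week sends from activation until the window end."""
    per_week = cfg.notifications_per_week
    offsets = np.arange(per_week) * (7 // per_week if per_week <= 3 else 1)
    offsets = np.asarray(sorted(set(int(o) for o in offsets)))[:per_week]
    if len(offsets) < per_week:  # dense schedules: consecutive days
        offsets = np.arange(per_week)

    avail = np.maximum((window_end - activation).dt.days.to_numpy(), 0)
    frames = []
    for o in offsets:
        counts = np.where(avail > o, (avail - o + 6) // 7, 0).astype(int)
        rep = np.repeat(np.arange(len(pid_arr)), counts)
        week = np.concatenate([np.arange(c) for c in counts]) if counts.sum() else \
            np.array([], dtype=int)
        day = o + 7 * week
        ts = activation.to_numpy()[rep] + (day * 86_400_000_000_000
                                           ).astype("timedelta64[ns]")
        ts = ts + np.timedelta64(9, "h")
        frames.append(pd.DataFrame({
            "participant_id": pid_arr[rep], "sent_timestamp": ts,
            "_theta": theta[rep], "_dob": dob.to_numpy()[rep]}))
    out = pd.concat(frames, ignore_index=True)
    age_days = (out["sent_timestamp"] - out["_dob"]).dt.days.to_numpy()
    decay = np.select([age_days < 91, age_days < 182], [0, 1], 2)
    p_open = np.clip(cfg.open_prob_scale * out["_theta"].to_numpy()
                     * np.asarray(cfg.period_decay)[decay], 0.0, 1.0)
    out["opened"] = rng.random(len(out)) < p_open
    out["channel"] = "push"
    return out[["participant_id", "channel", "sent_timestamp", "opened"]]


def simulate_cohort(config: SimulationConfig | None = None,
                    ) -> tuple[CohortDataset, GroundTruth]:
    """Generate one cohort plus its ground truth; deterministic per seed."""
    cfg = (config or SimulationConfig()).validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    pid_arr = np.array([f"P{i:04d}" for i in range(1, n + 1)])

    cov = _covariates(rng, cfg)
    start = pd.Timestamp(cfg.start_date)
    dob = pd.Series(start + pd.to_timedelta(
        rng.integers(0, 365, size=n), unit="D"))
    # truncated normal (no pile-up at the eligibility boundary): infant age
    # at registration between -6 weeks (antenatal enrolment) and 13 weeks
    age_lo, age_hi = -6.0, 13.0
    mu_a = cfg.mean_infant_age_at_registration_weeks
    sd_a = cfg.sd_infant_age_at_registration_weeks
    if sd_a > 0:
        age_reg_weeks = truncnorm.rvs((age_lo - mu_a) / sd_a,
                                      (age_hi - mu_a) / sd_a,
                                      loc=mu_a, scale=sd_a, size=n,
                                      random_state=rng)
    else:
        age_reg_weeks = np.full(n, mu_a)
    reg_offset_days = np.round(age_reg_weeks * 7.0).astype(int)
    registration = dob + pd.to_timedelta(reg_offset_days, unit="D")
    infant_age_weeks = reg_offset_days / 7.0

    eta = _latent_eta(rng, cfg, cov, infant_age_weeks)
    theta = _expit(eta)

    # activation: geometric-like delay shrinking with theta
    delay_mean = cfg.activation_delay_scale * (1.0 - theta) / np.clip(theta, 0.05, None)
    delay = rng.geometric(1.0 / (1.0 + delay_mean)) - 1
    activation = registration + pd.to_timedelta(delay, unit="D")
    window_end = dob + pd.Timedelta(days=273)
    activated = activation < window_end

    participants = pd.DataFrame({
        "participant_id": pid_arr,
        "registration_date": registration,
        "infant_dob": dob,
        "first_activation_date": activation.where(activated, pd.NaT),
    }).join(cov)
    participants["infant_age_at_T1_weeks"] = infant_age_weeks

    # --- sessions: per-period overdispersed counts, exposure-scaled --------
    sess_frames = []
    period_edges = [(0, 91), (91, 182), (182, 273)]
    act_clip = activation.where(activated, window_end)  # no exposure if never
    for j, (lo, hi) in enumerate(period_edges):
        p_start = dob + pd.to_timedelta(lo, unit="D")
        p_end = dob + pd.to_timedelta(hi, unit="D")
        eff_start = np.maximum(act_clip.to_numpy(), p_start.to_numpy())
        span = (p_end.to_numpy() - eff_start) / np.timedelta64(1, "D")
        # usage is activation-anchored (an initial burst that decays by
        # period), not proportional to the exposed fraction of the period;
        # a period that ended before activation simply has no sessions
        mu = cfg.session_rate * theta * cfg.period_decay[j]
        counts = _negbin(rng, mu, cfg.session_dispersion)
        counts = np.where(span > 0, counts, 0)
        rep = np.repeat(np.arange(n), counts)
        if len(rep) == 0:
            continue
        span_rep = np.repeat(np.maximum(span, 0.0), counts)
        offs = rng.random(len(rep)) * span_rep
        ts = pd.Series(eff_start[rep]) + pd.to_timedelta(
            np.floor(offs * 86400.0), unit="s")
        # depth declines alongside frequency: early sessions are the deep ones
        pages_mu = (cfg.pages_mean_base
                    + cfg.pages_mean_slope * theta[rep]) * cfg.period_decay[j]
        pages = 1 + _negbin(rng, pages_mu, cfg.pages_dispersion)
        sess_frames.append(pd.DataFrame({
            "participant_id": pid_arr[rep],
            "start_timestamp": ts.to_numpy(),
            "pages_viewed": pages.astype(int)}))
    sessions = (pd.concat(sess_frames, ignore_index=True) if sess_frames
                else pd.DataFrame(columns=["participant_id", "start_timestamp",
                                           "pages_viewed"]))
    sessions = sessions.sort_values(
        ["participant_id", "start_timestamp"], kind="mergesort",
        ignore_index=True)

    # --- messages -----------------------------------------------------------
    act_idx = np.flatnonzero(activated)
    pushes = _push_schedule(
        rng, cfg, pid_arr[act_idx],
        pd.Series(activation.to_numpy()[act_idx]),
        pd.Series(window_end.to_numpy()[act_idx]),
        pd.Series(dob.to_numpy()[act_idx]), theta[act_idx]) if len(act_idx) \
        else pd.DataFrame(columns=["participant_id", "channel",
                                   "sent_timestamp", "opened"])

    both = (cov["system"].to_numpy() == "both_app_and_email") & activated.to_numpy()
    email_frames = []
    if both.any():
        idx = np.flatnonzero(both)
        email_start = np.maximum(
            activation.to_numpy()[idx],
            (dob + pd.Timedelta(days=int(cfg.email_from_infant_week * 7))
             ).to_numpy()[idx])
        avail = ((window_end.to_numpy()[idx] - email_start)
                 / np.timedelta64(1, "D")).astype(int)
        counts = np.maximum((avail + 6) // 7, 0)
        rep = np.repeat(idx, counts)
        week = (np.concatenate([np.arange(c) for c in counts])
                if counts.sum() else np.array([], dtype=int))
        ts = (np.repeat(email_start, counts)
              + (week * 7 * 86_400_000_000_000).astype("timedelta64[ns]")
              + np.timedelta64(8, "h"))
        p_open = np.clip(cfg.email_open_prob_scale * theta[rep], 0.0, 1.0)
        email_frames.append(pd.DataFrame({
            "participant_id": pid_arr[rep], "channel": "email",
            "sent_timestamp": ts,
            "opened": rng.random(len(rep)) < p_open}))
    messages = pd.concat([pushes] + email_frames, ignore_index=True)
    messages = messages.sort_values(
        ["participant_id", "sent_timestamp", "channel"], kind="mergesort",
        ignore_index=True)
    messages["sent_timestamp"] = pd.to_datetime(messages["sent_timestamp"])
    messages["opened"] = messages["opened"].astype(bool)

    # --- survey -------------------------------------------------------------
    p_complete = _expit(_logit(cfg.survey_completion_prob)
                        + cfg.survey_completion_slope * eta)
    completed = rng.random(n) < p_complete
    website = completed & (rng.random(n) < cfg.website_user_prob)
    p_item = np.clip(0.4 * theta ** 2, 0.0, 0.95)

    responses = np.full((n, len(ITEM_COLUMNS)), "NA", dtype=object)
    extreme = rng.random((n, len(ITEM_COLUMNS))) < p_item[:, None]
    likert_alts = np.array(["agree", "neutral", "disagree", "didnt_use"])
    alt_draw = rng.integers(0, len(likert_alts), size=(n, len(ITEM_COLUMNS)))
    receipt_draw = _choice(rng, {"received_push": 0.8, "received_text": 0.1,
                                 "disabled": 0.1}, n)
    answer = completed & ~website
    for k, item in enumerate(DEFAULT_SCORING_KEY):
        if item.polarity == RECEIPT:
            responses[answer, k] = receipt_draw[answer]
        else:
            pos = "strongly_agree" if item.polarity == POSITIVE else "strongly_disagree"
            col = np.where(extreme[:, k], pos, likert_alts[alt_draw[:, k]])
            responses[answer, k] = col[answer]
    surveys = pd.DataFrame({"participant_id": pid_arr,
                            "completed_T3": completed,
                            "website_user": website})
    for k, col in enumerate(ITEM_COLUMNS):
        surveys[col] = responses[:, k]

    dataset = CohortDataset(participants, sessions, messages, surveys).validate()

    terciles = np.quantile(theta, [1 / 3, 2 / 3])
    stratum = np.select([theta <= terciles[0], theta <= terciles[1]],
                        ["low", "mid"], "high")
    truth = GroundTruth(
        frame=pd.DataFrame({"participant_id": pid_arr, "theta": theta,
                            "stratum": stratum}),
        effect_sizes=dict(cfg.effect_sizes))
    return dataset, truth


def null_cohort(config: SimulationConfig | None = None,
                ) -> tuple[CohortDataset, GroundTruth]:
    """As :func:`simulate_cohort` with every covariate effect set to zero."""
    cfg = (config or SimulationConfig()).validate()
    zeroed = {k: 0.0 for k in cfg.effect_sizes}
    return simulate_cohort(replace(cfg, effect_sizes=zeroed))
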