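"""The five engagement subindices.

Each participant i receives five scores in [0, 1]:

* **click depth** C_i — per period, the proportion of sessions in which at
  least ``page_threshold`` pages (default 2, the cohort median) were viewed;
* **loyalty** L_i — per period, a transform of the session count s: by
  default the web-analytics convention 1 - 1/s (more sessions, more loyal),
  with the literal reading 1/s available via config;
* **interaction** I_i — per period, push notifications opened / sent;
* **recency** R_i — period 1: reciprocal of the days from registration to
  first access; periods 2 and 3: reciprocal of the mean gap in days between
  consecutive sessions inside the period;
* **feedback** F_i — fraction of the 37 end-of-program satisfaction items
  answered at the extreme positive response (polarity-aware: reverse-worded
  items count "strongly disagree" as positive; the push-receipt item counts
  either delivery channel as positive).

C, L, I, R are each averaged over the three infant-age periods; a period
with no qualifying activity contributes 0 (non-use is zero engagement, never
a dropped term). F comes from the single end-of-program survey: participants
who did not complete it score 0, and the few who reported using the website
instead of the app were not asked the feedback items, so F is *unavailable*
(not zero) for them and the composite later averages over four subindices.

Two equivalent computation paths are provided: :func:`compute_subindices`
(one participant, plainly written) and :func:`score_cohort` (vectorized over
the whole cohort); they agree to floating-point identity and are
cross-checked in the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import ITEM_COLUMNS, N_SURVEY_ITEMS, CohortDataset
from .windowing import (DEFAULT_PERIOD_BOUNDARIES_WEEKS, PERIODS,
                        assign_period_from_age_days)

_DAY_SECONDS = 86400.0

# --- configuration ----------------------------------------------------------


@dataclass(frozen=True)
class EngagementConfig:
    """Conventions used when scoring a cohort.

    page_threshold
        Minimum pages viewed for a session to count as "deep" (default 2).
    loyalty_convention
        ``"wad"`` — 1 - 1/s, rising with session count (default); or
        ``"literal"`` — 1/s, the literal reciprocal.
    interaction_channels
        Message channels entering the interaction subindex; push only by
        default (weekly emails can be added for sensitivity analysis).
    recency_zero_day_value
        Recency value assigned for a zero-day activation delay.
    period_boundaries_weeks
        Upper infant-age boundary of each period.
    """

    page_threshold: int = 2
    loyalty_convention: str = "wad"
    interaction_channels: frozenset = frozenset({"push"})
    recency_zero_day_value: float = 1.0
    period_boundaries_weeks: tuple = DEFAULT_PERIOD_BOUNDARIES_WEEKS

    def __post_init__(self):
        if self.page_threshold < 1:
            raise ValueError("page_threshold must be >= 1")
        if self.loyalty_convention not in ("wad", "literal"):
            raise ValueError("loyalty_convention must be 'wad' or 'literal'")


# --- feedback scoring key ---------------------------------------------------

POSITIVE, NEGATIVE, RECEIPT = "positive", "negative", "receipt"


@dataclass(frozen=True)
class ScoringItem:
    id: str
    polarity: str  # positive | negative | receipt

    def score(self, response: str) -> int:
        if self.polarity == POSITIVE:
            return int(response == "strongly_agree")
        if self.polarity == NEGATIVE:
            return int(response == "strongly_disagree")
        return int(response in ("received_push", "received_text"))


@dataclass(frozen=True)
class ScoringKey:
    """Ordered polarity key for the 37 feedback items."""

    items: tuple

    def __post_init__(self):
        if len(self.items) != N_SURVEY_ITEMS:
            raise ValueError(
                f"scoring key must have {N_SURVEY_ITEMS} items, got {len(self.items)}")

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)


def _key(pairs: Iterable[tuple[str, str]]) -> ScoringKey:
    return ScoringKey(tuple(ScoringItem(i, p) for i, p in pairs))


#: Default key: item order and polarities of the shipped 37-item
#: satisfaction questionnaire. Seven reverse-worded items score
#: "strongly disagree" as the extreme positive; the push-receipt item
#: (item 30) scores either delivery channel as positive.
DEFAULT_SCORING_KEY = _key([
    ("easy_to_use", POSITIVE),
    ("liked_layout", POSITIVE),
    ("hard_to_navigate", NEGATIVE),
    ("quick_to_load", POSITIVE),
    ("failed_to_work", NEGATIVE),
    ("sections_worked_together", POSITIVE),
    ("language_easy", POSITIVE),
    ("did_everything_expected", POSITIVE),
    ("couldnt_find_answers", NEGATIVE),
    ("had_to_use_search", POSITIVE),
    ("enjoyable_experience", POSITIVE),
    ("found_app_complicated", NEGATIVE),
    ("trust_information", POSITIVE),
    ("felt_confident", POSITIVE),
    ("info_for_mums_useful", POSITIVE),
    ("feed_sleep_info_useful", POSITIVE),
    ("breastfeeding_info_useful", POSITIVE),
    ("formula_info_useful", POSITIVE),
    ("mixed_feeding_info_useful", POSITIVE),
    ("solid_feeding_info_useful", POSITIVE),
    ("videos_useful", POSITIVE),
    ("recipes_useful", POSITIVE),
    ("shared_with_friends_family", POSITIVE),
    ("concerned_internet_data", NEGATIVE),
    ("info_easy_to_understand", POSITIVE),
    ("liked_program_overall", POSITIVE),
    ("would_recommend", POSITIVE),
    ("helpful_to_share_with_carer", POSITIVE),
    ("covered_everything_wanted", POSITIVE),
    ("received_push_notifications", RECEIPT),
    ("notifications_disappeared", NEGATIVE),
    ("couldnt_retrieve_notifications", NEGATIVE),
    ("prefer_text_messages", POSITIVE),
    ("happy_with_message_frequency", POSITIVE),
    ("happy_with_message_timing", POSITIVE),
    ("messages_helpful", POSITIVE),
    ("messages_suited_age", POSITIVE),
])


# --- per-period scalar operations -------------------------------------------

def click_depth_period(pages_viewed: Sequence[int], page_threshold: int = 2) -> float:
    """Proportion of sessions reaching the page threshold; 0 if no sessions."""
    pages = list(pages_viewed)
    if not pages:
        return 0.0
    deep = sum(1 for p in pages if p >= page_threshold)
    return deep / len(pages)


def loyalty_period(session_count: int, convention: str = "wad") -> float:
    """Loyalty component from a period's session count s.

    ``wad``: 1 - 1/s (0 when s = 0); ``literal``: 1/s (0 when s = 0).
    """
    if session_count <= 0:
        return 0.0
    if convention == "wad":
        return 1.0 - 1.0 / session_count
    if convention == "literal":
        return 1.0 / session_count
    raise ValueError(f"unknown loyalty convention: {convention!r}")


def interaction_period(opened: int, sent: int) -> float:
    """Opened / sent for one period's push notifications; 0 if none sent."""
    if sent <= 0:
        return 0.0
    return opened / sent


def _reciprocal_days(days: float, zero_day_value: float) -> float:
    # sub-day values cap at 1.0 so the component stays inside [0, 1]
    if days == 0:
        return zero_day_value
    if days < 1.0:
        return 1.0
    return 1.0 / days


def recency_components(registration_date, session_timestamps: Sequence,
                       infant_dob, config: EngagementConfig | None = None,
                       ) -> tuple[float, float, float]:
    """The three recency components for one participant.

    ``session_timestamps`` must already be restricted to the observation
    window. R1 is the reciprocal of the activation delay in days
    (registration to first session, whichever period it falls in); R2 and R3
    are reciprocals of the mean gap in days between consecutive sessions
    whose start falls inside the respective period. Undefined components
    (no session; fewer than two sessions in the period) are 0.
    """
    config = config or EngagementConfig()
    ts = sorted(pd.Timestamp(t) for t in session_timestamps)
    if not ts:
        return (0.0, 0.0, 0.0)
    reg = pd.Timestamp(registration_date)
    dob = pd.Timestamp(infant_dob)
    delay_days = (ts[0] - reg).total_seconds() / _DAY_SECONDS
    r1 = _reciprocal_days(delay_days, config.recency_zero_day_value)

    edges = [b * 7.0 for b in config.period_boundaries_weeks]
    out = [r1]
    for j in (2, 3):
        lo, hi = edges[j - 2], edges[j - 1]
        in_period = [t for t in ts
                     if lo <= (t - dob).total_seconds() / _DAY_SECONDS < hi]
        if len(in_period) < 2:
            out.append(0.0)
            continue
        gaps = [(b - a).total_seconds() / _DAY_SECONDS
                for a, b in zip(in_period, in_period[1:])]
        mean_gap = sum(gaps) / len(gaps)
        out.append(1.0 if mean_gap < 1.0 else 1.0 / mean_gap)
    return tuple(out)


def feedback_score(completed_T3: bool, website_user: bool,
                   items: Sequence[str] | None,
                   scoring_key: ScoringKey = DEFAULT_SCORING_KEY,
                   ) -> float | None:
    """Feedback subindex for one participant, or ``None`` when unavailable.

    Website users were not asked the feedback items -> unavailable (the
    composite then averages four subindices). Non-completers score 0 on all
    37 items. ``didnt_use`` and ``NA`` responses score 0.
    """
    if website_user:
        return None
    if not completed_T3:
        return 0.0
    items = list(items or [])
    if len(items) != len(scoring_key):
        raise ValueError(
            f"completed survey must have {len(scoring_key)} items, got {len(items)}")
    total = sum(item.score(resp) for item, resp in zip(scoring_key, items))
    return total / len(scoring_key)


# --- per-participant scores -------------------------------------------------

@dataclass
class SubindexScores:
    """All subindex components for one participant (houses C, L, I, R, F)."""

    participant_id: str
    click_depth_periods: tuple[float, float, float]
    loyalty_periods: tuple[float, float, float]
    interaction_periods: tuple[float, float, float]
    recency_periods: tuple[float, float, float]
    fi: float | None  # None when the participant was not asked for feedback

    @property
    def ci(self) -> float:
        return sum(self.click_depth_periods) / 3.0

    @property
    def li(self) -> float:
        return sum(self.loyalty_periods) / 3.0

    @property
    def ii(self) -> float:
        return sum(self.interaction_periods) / 3.0

    @property
    def ri(self) -> float:
        return sum(self.recency_periods) / 3.0

    @property
    def fi_available(self) -> bool:
        return self.fi is not None

    def available_subindices(self) -> list[float]:
        vals = [self.ci, self.li, self.ii, self.ri]
        if self.fi is not None:
            vals.append(self.fi)
        return vals


def compute_subindices(participant_id: str, dataset: CohortDataset,
                       config: EngagementConfig | None = None,
                       scoring_key: ScoringKey = DEFAULT_SCORING_KEY,
                       ) -> SubindexScores:
    """Score one participant by direct per-period computation."""
    config = config or EngagementConfig()
    row = dataset.participants.loc[
        dataset.participants["participant_id"] == participant_id]
    if row.empty:
        raise KeyError(f"unknown participant: {participant_id}")
    reg = pd.Timestamp(row["registration_date"].iloc[0])
    dob = pd.Timestamp(row["infant_dob"].iloc[0])
    edges = [b * 7.0 for b in config.period_boundaries_weeks]
    window_end = dob + pd.Timedelta(days=edges[-1])

    def in_window(ts: pd.Timestamp) -> bool:
        return reg <= ts < window_end

    def period_of(ts: pd.Timestamp) -> int:
        age = (ts - dob).total_seconds() / _DAY_SECONDS
        for j, upper in zip(PERIODS, edges):
            if age < upper:
                return j
        return 0

    sess = dataset.sessions[dataset.sessions["participant_id"] == participant_id]
    sess_events = [(pd.Timestamp(t), int(p)) for t, p in
                   zip(sess["start_timestamp"], sess["pages_viewed"])
                   if in_window(pd.Timestamp(t))]
    msgs = dataset.messages[
        (dataset.messages["participant_id"] == participant_id)
        & (dataset.messages["channel"].isin(config.interaction_channels))]
    msg_events = [(pd.Timestamp(t), bool(o)) for t, o in
                  zip(msgs["sent_timestamp"], msgs["opened"])
                  if in_window(pd.Timestamp(t))]

    c, l, i = [], [], []
    for j in PERIODS:
        pages_j = [p for t, p in sess_events if period_of(t) == j]
        c.append(click_depth_period(pages_j, config.page_threshold))
        l.append(loyalty_period(len(pages_j), config.loyalty_convention))
        sent_j = [o for t, o in msg_events if period_of(t) == j]
        i.append(interaction_period(sum(sent_j), len(sent_j)))

    r = recency_components(reg, [t for t, _ in sess_events], dob, config)

    srow = dataset.surveys.loc[
        dataset.surveys["participant_id"] == participant_id]
    if srow.empty:
        fi = feedback_score(False, False, None, scoring_key)
    else:
        fi = feedback_score(bool(srow["completed_T3"].iloc[0]),
                            bool(srow["website_user"].iloc[0]),
                            [srow[c_].iloc[0] for c_ in ITEM_COLUMNS],
                            scoring_key)
    return SubindexScores(participant_id, tuple(c), tuple(l), tuple(i), r, fi)


# --- vectorized cohort scoring ----------------------------------------------

def _period_frame(dataset: CohortDataset, events: pd.DataFrame,
                  ts_col: str, boundaries) -> pd.DataFrame:
    """Merge registry dates, filter to the window, and attach period labels."""
    merged = events.merge(
        dataset.participants[["participant_id", "registration_date", "infant_dob"]],
        on="participant_id", how="left")
    age_days = ((merged[ts_col] - merged["infant_dob"])
                .dt.total_seconds() / _DAY_SECONDS)
    in_win = ((merged[ts_col] >= merged["registration_date"])
              & (age_days < boundaries[-1] * 7.0))
    merged = merged.loc[in_win].copy()
    merged["age_days"] = age_days[in_win]
    merged["period"] = assign_period_from_age_days(
        merged["age_days"].to_numpy(), boundaries)
    return merged


def _wide(series: pd.Series, pids: pd.Index, prefix: str) -> pd.DataFrame:
    wide = series.unstack("period").reindex(index=pids, columns=list(PERIODS))
    wide = wide.fillna(0.0)
    wide.columns = [f"{prefix}{j}" for j in PERIODS]
    return wide


def score_cohort(dataset: CohortDataset,
                 config: EngagementConfig | None = None,
                 scoring_key: ScoringKey = DEFAULT_SCORING_KEY,
                 ) -> pd.DataFrame:
    """Compute every subindex component for every participant.

    Returns one row per registry participant with per-period components
    (``c1..c3``, ``l1..l3``, ``i1..i3``, ``r1..r3``), the period-averaged
    subindices (``ci``, ``li``, ``ii``, ``ri``), ``fi`` (NaN when the
    feedback index is unavailable) and ``fi_available``.
    """
    config = config or EngagementConfig()
    bounds = config.period_boundaries_weeks
    pids = pd.Index(dataset.participants["participant_id"], name="participant_id")
    reg = dataset.participants.set_index("participant_id")["registration_date"]

    sess = _period_frame(dataset, dataset.sessions, "start_timestamp", bounds)
    grp = sess.groupby(["participant_id", "period"])
    n_sessions = grp.size().astype(float)
    deep = (sess["pages_viewed"] >= config.page_threshold).groupby(
        [sess["participant_id"], sess["period"]]).sum().astype(float)

    c_wide = _wide(deep / n_sessions, pids, "c")
    if config.loyalty_convention == "wad":
        loyal = 1.0 - 1.0 / n_sessions
    else:
        loyal = 1.0 / n_sessions
    l_wide = _wide(loyal, pids, "l")

    # recency: activation delay, then within-period mean gaps for periods 2, 3
    first = sess.groupby("participant_id")["start_timestamp"].min()
    delay = ((first - reg.reindex(first.index))
             .dt.total_seconds() / _DAY_SECONDS)
    r1 = pd.Series(
        np.where(delay == 0, config.recency_zero_day_value,
                 np.where(delay < 1.0, 1.0, 1.0 / np.maximum(delay, 1.0))),
        index=first.index)
    r1 = r1.reindex(pids).fillna(0.0)

    late = sess[sess["period"] >= 2].sort_values(
        ["participant_id", "period", "start_timestamp"], kind="mergesort")
    gap_grp = late.groupby(["participant_id", "period"])
    gaps = gap_grp["start_timestamp"].diff().dt.total_seconds() / _DAY_SECONDS
    mean_gap = gaps.groupby(
        [late["participant_id"], late["period"]]).mean()
    counts = gap_grp.size()
    mean_gap = mean_gap.reindex(counts.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_late = pd.Series(
            np.where(counts < 2, 0.0,
                     np.where(mean_gap < 1.0, 1.0, 1.0 / mean_gap)),
            index=counts.index)
    r_wide = _wide(r_late, pids, "r")
    r_wide["r1"] = r1.to_numpy()

    msgs = dataset.messages[
        dataset.messages["channel"].isin(config.interaction_channels)]
    msgs = _period_frame(dataset, msgs, "sent_timestamp", bounds)
    mgrp = msgs.groupby(["participant_id", "period"])
    sent = mgrp.size().astype(float)
    opened = mgrp["opened"].sum().astype(float)
    i_wide = _wide(opened / sent, pids, "i")

    scores = pd.concat([c_wide, l_wide, i_wide, r_wide[["r1", "r2", "r3"]]], axis=1)
    for prefix, name in (("c", "ci"), ("l", "li"), ("i", "ii"), ("r", "ri")):
        scores[name] = (scores[f"{prefix}1"] + scores[f"{prefix}2"]
                        + scores[f"{prefix}3"]) / 3.0

    scores["fi"] = _feedback_frame(dataset, pids, scoring_key)
    scores["fi_available"] = scores["fi"].notna()
    return scores.reset_index()


def _feedback_frame(dataset: CohortDataset, pids: pd.Index,
                    scoring_key: ScoringKey) -> pd.Series:
    surveys = dataset.surveys.set_index("participant_id")
    total = pd.Series(0.0, index=surveys.index)
    for col, item in zip(ITEM_COLUMNS, scoring_key):
        vals = surveys[col]
        if item.polarity == POSITIVE:
            total += (vals == "strongly_agree").astype(float)
        elif item.polarity == NEGATIVE:
            total += (vals == "strongly_disagree").astype(float)
        else:
            total += vals.isin(["received_push", "received_text"]).astype(float)
    fi = total / float(len(scoring_key))
    fi[~surveys["completed_T3"]] = 0.0
    fi[surveys["website_user"]] = np.nan
    fi = fi.reindex(pids)
    # participants with no survey row at all: not completed -> 0
    fi[~pids.isin(surveys.index)] = 0.0
    return fi
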