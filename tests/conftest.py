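"""Shared fixtures: hand-built cohorts with known engagement scores."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mhealth_ei.data_model import ITEM_COLUMNS, CohortDataset
from mhealth_ei.subindices import DEFAULT_SCORING_KEY, POSITIVE

DEFAULT_COVARIATES = {
    "mother_age_years": 30.0, "education": "degree",
    "employment": "working_or_studying", "income": "average",
    "marital": "relationship", "parity": "primiparous",
    "recruitment": "practitioner", "device": "ios", "system": "app_only",
    "country_of_birth": "australia", "infant_birth_weight_g": 3400.0,
    "infant_sex": "female", "baseline_feeding": "breastfeeding",
    "infant_age_at_T1_weeks": 6.0,
}

POLARITY = [item.polarity for item in DEFAULT_SCORING_KEY]


def make_participant(pid, dob, registration, activation=None, **covariates):
    row = {"participant_id": pid, "infant_dob": pd.Timestamp(dob),
           "registration_date": pd.Timestamp(registration),
           "first_activation_date": (pd.Timestamp(activation)
                                     if activation else pd.NaT)}
    row.update(DEFAULT_COVARIATES)
    row.update(covariates)
    return row


def make_survey_row(pid, completed=True, website=False, extreme_positive=0):
    """Survey row with exactly ``extreme_positive`` scoring items.

    The first n positive-polarity items get the extreme response; every
    other item gets a zero-scoring response.
    """
    row = {"participant_id": pid, "completed_T3": completed,
           "website_user": website}
    remaining = extreme_positive
    for col, item in zip(ITEM_COLUMNS, DEFAULT_SCORING_KEY):
        if not completed or website:
            row[col] = "NA"
        elif item.polarity == POSITIVE and remaining > 0:
            row[col] = "strongly_agree"
            remaining -= 1
        elif item.polarity == "receipt":
            row[col] = "disabled"
        else:
            row[col] = "agree"
    assert remaining == 0, "not enough positive items for requested score"
    return row


def build_dataset(participants, sessions=(), messages=(), surveys=()):
    pframe = pd.DataFrame(participants)
    sframe = pd.DataFrame(list(sessions),
                          columns=["participant_id", "start_timestamp",
                                   "pages_viewed"])
    sframe["start_timestamp"] = pd.to_datetime(sframe["start_timestamp"])
    sframe["pages_viewed"] = sframe["pages_viewed"].astype(int) \
        if len(sframe) else sframe["pages_viewed"]
    mframe = pd.DataFrame(list(messages),
                          columns=["participant_id", "channel",
                                   "sent_timestamp", "opened"])
    mframe["sent_timestamp"] = pd.to_datetime(mframe["sent_timestamp"])
    if len(mframe):
        mframe["opened"] = mframe["opened"].astype(bool)
    vframe = (pd.DataFrame(list(surveys)) if len(list(surveys)) else
              pd.DataFrame(columns=["participant_id", "completed_T3",
                                    "website_user"] + ITEM_COLUMNS))
    return CohortDataset(pframe, sframe, mframe, vframe).validate()


DOB = pd.Timestamp("2015-03-01")
REG = DOB + pd.Timedelta(days=63)  # registered at infant age 9 weeks


@pytest.fixture
def worked_example():
    """The fully hand-computed participant plus expected exact values.

    P0001 registers at infant age 9 weeks, activates the next day, has 3
    period-1 sessions (all at or above the 2-page threshold), opens 6 of
    12 period-1 pushes and none of the 39+39 later ones, and answers 10 of
    37 survey items at the extreme positive.
    """
    pid = "P0001"
    sessions = [
        (pid, DOB + pd.Timedelta(days=64), 3),   # 1 day after registration
        (pid, DOB + pd.Timedelta(days=70), 2),
        (pid, DOB + pd.Timedelta(days=80), 5),
    ]
    messages = []
    for k in range(12):  # period 1: 12 sent, first 6 opened
        messages.append((pid, "push", DOB + pd.Timedelta(days=64 + 2 * k),
                         k < 6))
    for k in range(39):  # period 2: 39 sent, none opened
        messages.append((pid, "push", DOB + pd.Timedelta(days=91 + 2 * k),
                         False))
    for k in range(39):  # period 3: 39 sent, none opened
        messages.append((pid, "push", DOB + pd.Timedelta(days=182 + 2 * k),
                         False))
    dataset = build_dataset(
        [make_participant(pid, DOB, REG, REG + pd.Timedelta(days=1))],
        sessions, messages,
        [make_survey_row(pid, extreme_positive=10)])
    expected = {
        "ci": 1.0 / 3.0,
        "li": (2.0 / 3.0) / 3.0,
        "ii": (0.5 + 0.0 + 0.0) / 3.0,
        "ri": (1.0 + 0.0 + 0.0) / 3.0,
        "fi": 10.0 / 37.0,
        "ei": 100.0 * (1.0 / 3.0 + 2.0 / 9.0 + 1.0 / 6.0 + 1.0 / 3.0
                       + 10.0 / 37.0) / 5.0,
    }
    return dataset, expected


@pytest.fixture
def small_cohort():
    """Five hand-built participants covering the scoring edge cases."""
    rows = [make_participant("P0001", DOB, REG, REG + pd.Timedelta(days=1))]
    sessions = [
        ("P0001", DOB + pd.Timedelta(days=64), 3),
        ("P0001", DOB + pd.Timedelta(days=70), 2),
        ("P0001", DOB + pd.Timedelta(days=80), 5),
    ]
    messages = [("P0001", "push", DOB + pd.Timedelta(days=64 + 2 * k), k < 6)
                for k in range(12)]
    surveys = [make_survey_row("P0001", extreme_positive=10)]

    # P0002: website user (feedback unavailable), steady sessions
    rows.append(make_participant("P0002", DOB, DOB + pd.Timedelta(days=7)))
    for d in (10, 30, 95, 103, 200, 214):
        sessions.append(("P0002", DOB + pd.Timedelta(days=d), 1 + d % 4))
    surveys.append(make_survey_row("P0002", website=True))

    # P0003: never used the app, never surveyed -> EI 0
    rows.append(make_participant("P0003", DOB, DOB + pd.Timedelta(days=14)))

    # P0004: survey non-completer with some usage
    rows.append(make_participant("P0004", DOB, DOB + pd.Timedelta(days=21)))
    for d in (25, 26, 150):
        sessions.append(("P0004", DOB + pd.Timedelta(days=d), 2))
    for k in range(10):
        messages.append(("P0004", "push", DOB + pd.Timedelta(days=30 + 7 * k),
                         k % 3 == 0))
    surveys.append(make_survey_row("P0004", completed=False))

    # P0005: email-channel user; emails excluded from interaction by default
    rows.append(make_participant("P0005", DOB, DOB + pd.Timedelta(days=28),
                                 system="both_app_and_email"))
    sessions.append(("P0005", DOB + pd.Timedelta(days=40), 6))
    for k in range(8):
        messages.append(("P0005", "email", DOB + pd.Timedelta(days=40 + 7 * k),
                         True))
    surveys.append(make_survey_row("P0005", extreme_positive=20))

    return build_dataset(rows, sessions, messages, surveys)
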