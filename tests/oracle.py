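"""Deliberately naive reference implementations used as independent oracles.

Everything here recomputes engagement quantities with direct Python loops
over individual event records and explicit date arithmetic — no pandas
grouping, no shared code with the package internals — so agreement with the
library is meaningful evidence of correctness.
"""
from __future__ import annotations

import math

import pandas as pd

DAY = 86400.0


def _days(a, b) -> float:
    return (b - a).total_seconds() / DAY


def _period(ts, dob) -> int:
    d = _days(dob, ts)
    if d < 91:
        return 1
    if d < 182:
        return 2
    if d < 273:
        return 3
    return 0


def naive_participant(reg, dob, sessions, push_messages, survey, polarity,
                      page_threshold=2, loyalty="wad", zero_day=1.0) -> dict:
    """Score one participant with explicit loops.

    sessions: list of (timestamp, pages); push_messages: list of
    (timestamp, opened); survey: None or (completed, website, [37 responses]);
    polarity: list of 37 strings in {positive, negative, receipt}.
    """
    wend = dob + pd.Timedelta(days=273)
    sess = sorted([(t, p) for (t, p) in sessions if reg <= t < wend],
                  key=lambda x: x[0])
    msgs = [(t, o) for (t, o) in push_messages if reg <= t < wend]

    c, l, i = [], [], []
    for j in (1, 2, 3):
        pages = [p for (t, p) in sess if _period(t, dob) == j]
        if pages:
            c.append(sum(1 for p in pages if p >= page_threshold) / len(pages))
            l.append(1.0 - 1.0 / len(pages) if loyalty == "wad"
                     else 1.0 / len(pages))
        else:
            c.append(0.0)
            l.append(0.0)
        sent = [o for (t, o) in msgs if _period(t, dob) == j]
        i.append(sum(1 for o in sent if o) / len(sent) if sent else 0.0)

    r = [0.0, 0.0, 0.0]
    if sess:
        d = _days(reg, sess[0][0])
        r[0] = zero_day if d == 0 else (1.0 if d < 1.0 else 1.0 / d)
    for j in (2, 3):
        tj = [t for (t, _) in sess if _period(t, dob) == j]
        if len(tj) >= 2:
            gaps = [_days(a, b) for a, b in zip(tj, tj[1:])]
            mg = sum(gaps) / len(gaps)
            r[j - 1] = 1.0 if mg < 1.0 else 1.0 / mg

    fi = 0.0
    if survey is not None:
        completed, website, answers = survey
        if website:
            fi = None
        elif not completed:
            fi = 0.0
        else:
            total = 0
            for pol, resp in zip(polarity, answers):
                if pol == "positive":
                    total += resp == "strongly_agree"
                elif pol == "negative":
                    total += resp == "strongly_disagree"
                else:
                    total += resp in ("received_push", "received_text")
            fi = total / 37.0

    ci = (c[0] + c[1] + c[2]) / 3.0
    li = (l[0] + l[1] + l[2]) / 3.0
    ii = (i[0] + i[1] + i[2]) / 3.0
    ri = (r[0] + r[1] + r[2]) / 3.0
    if fi is None:
        ei = 100.0 * (ci + li + ii + ri) / 4.0
        n_used = 4
    else:
        ei = 100.0 * (ci + li + ii + ri + fi) / 5.0
        n_used = 5
    return {"c": c, "l": l, "i": i, "r": r, "ci": ci, "li": li, "ii": ii,
            "ri": ri, "fi": fi, "ei": ei, "n_subindices_used": n_used}


def naive_cohort(dataset, polarity, **kw) -> dict:
    """Apply :func:`naive_participant` to every registry participant."""
    from mhealth_ei.data_model import ITEM_COLUMNS

    sess_by, msg_by, survey_by = {}, {}, {}
    for row in dataset.sessions.itertuples():
        sess_by.setdefault(row.participant_id, []).append(
            (row.start_timestamp, row.pages_viewed))
    for row in dataset.messages.itertuples():
        if row.channel == "push":
            msg_by.setdefault(row.participant_id, []).append(
                (row.sent_timestamp, bool(row.opened)))
    for row in dataset.surveys.itertuples():
        answers = [getattr(row, c) for c in ITEM_COLUMNS]
        survey_by[row.participant_id] = (bool(row.completed_T3),
                                         bool(row.website_user), answers)
    out = {}
    for row in dataset.participants.itertuples():
        out[row.participant_id] = naive_participant(
            row.registration_date, row.infant_dob,
            sess_by.get(row.participant_id, []),
            msg_by.get(row.participant_id, []),
            survey_by.get(row.participant_id), polarity, **kw)
    return out


def naive_percentile(values, q: float) -> float:
    """Linear-interpolation percentile from sorted order statistics."""
    v = sorted(float(x) for x in values)
    h = (len(v) - 1) * q
    lo, hi = math.floor(h), math.ceil(h)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def naive_ols(X, y):
    """Normal-equations least squares (for cross-checking model fits)."""
    import numpy as np

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)
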