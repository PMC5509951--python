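"""Observation window and infant-age periods.

Engagement is scored over the observation window running from the
registration date to the day the infant turns 39 weeks (9 months). Within
the window, events are assigned to one of three infant-age periods:

* period 1 ("initial"): infant age in [0, 13) weeks — events before birth
  (antenatal registration is allowed) also map here;
* period 2 ("interim"): [13, 26) weeks;
* period 3 ("final"): [26, 39) weeks.

Boundaries are half-open, so an event at exactly 13 or 26 weeks belongs to
the later period; events at or beyond 39 weeks fall outside the window. All
calendar arithmetic is in days (naive timestamps, no time zones), converted
to weeks as real numbers.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime
from typing import Sequence

import numpy as np
import pandas as pd

#: Upper infant-age boundary (weeks) of each period, in order.
DEFAULT_PERIOD_BOUNDARIES_WEEKS: tuple[float, float, float] = (13.0, 26.0, 39.0)

PERIODS = (1, 2, 3)
PERIOD_LABELS = {1: "initial", 2: "interim", 3: "final"}

_DAY_SECONDS = 86400.0


def _as_ts(value) -> pd.Timestamp:
    if isinstance(value, (date, datetime, str)):
        return pd.Timestamp(value)
    return value


def infant_age_weeks(event_date, infant_dob) -> float:
    """Infant age at ``event_date`` in (fractional) weeks.

    Negative for events before birth (sign convention: antenatal < 0).
    """
    delta = _as_ts(event_date) - _as_ts(infant_dob)
    return delta.total_seconds() / _DAY_SECONDS / 7.0


def assign_period(event_date, infant_dob,
                  boundaries: Sequence[float] = DEFAULT_PERIOD_BOUNDARIES_WEEKS,
                  ) -> int | None:
    """Map an event to its infant-age period, or ``None`` beyond the window."""
    age = infant_age_weeks(event_date, infant_dob)
    for j, upper in zip(PERIODS, boundaries):
        if age < upper:
            return j
    return None


def assign_period_from_age_days(
    age_days: np.ndarray,
    boundaries: Sequence[float] = DEFAULT_PERIOD_BOUNDARIES_WEEKS,
) -> np.ndarray:
    """Vectorized :func:`assign_period` on an infant-age-in-days array.

    Ages at or beyond the last boundary get period 0 (outside the window).
    """
    edges = np.asarray(boundaries, dtype=float) * 7.0
    out = np.select([age_days < edges[0], age_days < edges[1], age_days < edges[2]],
                    [1, 2, 3], default=0)
    return out


@dataclass(frozen=True)
class ObservationWindow:
    """Scoring window for one participant: registration to infant week 39."""

    start: pd.Timestamp
    end: pd.Timestamp

    @classmethod
    def for_participant(cls, registration_date, infant_dob,
                        boundaries=DEFAULT_PERIOD_BOUNDARIES_WEEKS,
                        ) -> "ObservationWindow":
        start = _as_ts(registration_date)
        end = _as_ts(infant_dob) + pd.Timedelta(days=boundaries[-1] * 7)
        return cls(start=start, end=end)

    def contains(self, ts) -> bool:
        ts = _as_ts(ts)
        return bool(self.start <= ts < self.end)


def filter_window(events: pd.DataFrame, registration_date, infant_dob,
                  timestamp_column: str = "start_timestamp",
                  boundaries: Sequence[float] = DEFAULT_PERIOD_BOUNDARIES_WEEKS,
                  ) -> pd.DataFrame:
    """Retain one participant's events inside the observation window.

    Keeps events with timestamp >= registration and infant age < the last
    period boundary (default 39 weeks). Idempotent.
    """
    window = ObservationWindow.for_participant(registration_date, infant_dob,
                                               boundaries)
    ts = pd.to_datetime(events[timestamp_column])
    keep = (ts >= window.start) & (ts < window.end)
    return events.loc[keep]
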