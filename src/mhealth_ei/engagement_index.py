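"""Composite engagement index, quartile cut-points and categorization.

The engagement index (EI) for participant i is

    EI_i = 100 * mean(available subindices)

i.e. 100 * (C_i + L_i + I_i + R_i + F_i) / 5 in the usual case, and an
average over the four app-derived subindices when the feedback index is
unavailable (website users, who were never asked the feedback items).
Survey non-completers keep all five terms with F_i = 0, which is the same
number as averaging a zero — but a different *count* than dropping it.

Cut-points are the cohort's EI quartiles under linear interpolation between
order statistics (the numpy default); a participant is **poor** when
EI <= Q1, **high** when EI >= Q3, **moderate** otherwise. Boundary ties go
to the outer categories.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .subindices import SubindexScores

CATEGORIES = ("poor", "moderate", "high")

#: Percentile rule used for the quartile cut-points (recorded in metadata).
PERCENTILE_METHOD = "linear"


@dataclass
class EngagementResult:
    """EI on the 0-100 scale for one participant."""

    participant_id: str
    ei: float
    n_subindices_used: int  # 5, or 4 when the feedback index is unavailable
    category: str | None = None


@dataclass(frozen=True)
class Cutpoints:
    """Cohort quartile cut-points on the EI scale."""

    q1: float
    q3: float

    def __post_init__(self):
        if self.q1 > self.q3:
            raise ValueError("q1 must be <= q3")


def combine(scores: SubindexScores) -> EngagementResult:
    """Fold one participant's subindices into the 0-100 composite."""
    vals = scores.available_subindices()
    ei = 100.0 * sum(vals) / len(vals)
    return EngagementResult(scores.participant_id, ei, len(vals))


def combine_frame(scores: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`combine` over a :func:`~mhealth_ei.subindices.score_cohort` frame.

    Adds ``ei`` and ``n_subindices_used`` columns.
    """
    out = scores.copy()
    four = out["ci"] + out["li"] + out["ii"] + out["ri"]
    available = out["fi"].notna()
    out["n_subindices_used"] = np.where(available, 5, 4)
    out["ei"] = np.where(available,
                         100.0 * (four + out["fi"].fillna(0.0)) / 5.0,
                         100.0 * four / 4.0)
    return out


def cohort_cutpoints(ei_values) -> Cutpoints:
    """Q1/Q3 of the cohort EI distribution (linear-interpolation percentiles)."""
    vals = np.asarray(ei_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 4:
        raise ValueError(f"need at least 4 EI values for quartiles, got {vals.size}")
    q1, q3 = np.percentile(vals, [25.0, 75.0], method=PERCENTILE_METHOD)
    return Cutpoints(q1=float(q1), q3=float(q3))


def categorize_value(ei: float, cutpoints: Cutpoints) -> str:
    """poor if EI <= Q1, high if EI >= Q3, moderate otherwise."""
    if ei <= cutpoints.q1:
        return "poor"
    if ei >= cutpoints.q3:
        return "high"
    return "moderate"


def categorize(result: EngagementResult, cutpoints: Cutpoints) -> EngagementResult:
    result.category = categorize_value(result.ei, cutpoints)
    return result


def categorize_frame(results: pd.DataFrame, cutpoints: Cutpoints) -> pd.DataFrame:
    """Add a ``category`` column to a results frame with an ``ei`` column."""
    out = results.copy()
    ei = out["ei"].to_numpy(dtype=float)
    out["category"] = np.select(
        [ei <= cutpoints.q1, ei >= cutpoints.q3], ["poor", "high"], "moderate")
    return out
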