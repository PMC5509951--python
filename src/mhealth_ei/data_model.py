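"""Domain types, validation, and delimited-text IO for engagement cohorts.

A cohort is four tables, each a plain CSV with a header row:

* a participant **registry** — one row per enrolled mother-infant dyad, with
  registration date, infant date of birth, optional first-activation date and
  the baseline covariates used in the determinant analysis;
* an app **session log** — one row per access session (participant, start
  timestamp, pages viewed);
* a **message log** — one row per push notification or weekly email sent
  (participant, channel, sent timestamp, opened flag);
* the end-of-program **survey** — one row per participant with a completion
  flag, a website-user flag and the 37 satisfaction items.

Tables are held in memory as :class:`pandas.DataFrame` objects inside a
:class:`CohortDataset`. Reading validates every row; rows that violate an
invariant (unknown enum value, non-positive page count, event for an unknown
participant, ...) are dropped with a per-reason count recorded in a
:class:`ReadReport` — real app exports are dirty, so dirt is logged, not
fatal. Two conditions *are* fatal: a missing input file and a duplicate
participant id.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# --- closed enum sets -------------------------------------------------------

EDUCATION_LEVELS = frozenset({"degree", "no_university"})
EMPLOYMENT_LEVELS = frozenset({"working_or_studying", "not_in_labor_force"})
INCOME_LEVELS = frozenset(
    {"no_response", "below_average", "average", "above_average", "higher_income"}
)
MARITAL_LEVELS = frozenset({"relationship", "single"})
PARITY_LEVELS = frozenset({"primiparous", "multiparous"})
RECRUITMENT_LEVELS = frozenset({"practitioner", "web_based", "family_or_friends"})
DEVICE_LEVELS = frozenset({"ios", "android"})
SYSTEM_LEVELS = frozenset({"app_only", "both_app_and_email"})
SEX_LEVELS = frozenset({"male", "female"})
FEEDING_LEVELS = frozenset({"breastfeeding", "formula_feeding", "mixed_feeding"})
CHANNEL_LEVELS = frozenset({"push", "email"})

#: Likert responses for ordinary satisfaction items.  ``didnt_use`` and ``NA``
#: both score zero; ``NA`` additionally stands in for "not asked".
LIKERT_RESPONSES = frozenset(
    {"strongly_agree", "agree", "neutral", "disagree", "strongly_disagree",
     "didnt_use", "NA"}
)
#: The push-receipt item has its own response set (it is not a Likert item).
RECEIPT_RESPONSES = frozenset({"received_push", "received_text", "disabled", "NA"})
ITEM_RESPONSES = LIKERT_RESPONSES | RECEIPT_RESPONSES

N_SURVEY_ITEMS = 37
ITEM_COLUMNS = [f"item_{k}" for k in range(1, N_SURVEY_ITEMS + 1)]

#: Eligibility: infants at most three months (13 weeks) old at registration.
MAX_REGISTRATION_AGE_DAYS = 13 * 7

COVARIATE_ENUMS: Mapping[str, frozenset] = {
    "education": EDUCATION_LEVELS,
    "employment": EMPLOYMENT_LEVELS,
    "income": INCOME_LEVELS,
    "marital": MARITAL_LEVELS,
    "parity": PARITY_LEVELS,
    "recruitment": RECRUITMENT_LEVELS,
    "device": DEVICE_LEVELS,
    "system": SYSTEM_LEVELS,
    "infant_sex": SEX_LEVELS,
    "baseline_feeding": FEEDING_LEVELS,
}

COVARIATE_NUMERIC = [
    "mother_age_years",
    "infant_birth_weight_g",
    "infant_age_at_T1_weeks",
]

REGISTRY_COLUMNS = (
    ["participant_id", "registration_date", "infant_dob", "first_activation_date"]
    + list(COVARIATE_ENUMS)
    + ["country_of_birth"]
    + COVARIATE_NUMERIC
)
SESSION_COLUMNS = ["participant_id", "start_timestamp", "pages_viewed"]
MESSAGE_COLUMNS = ["participant_id", "channel", "sent_timestamp", "opened"]
SURVEY_COLUMNS = ["participant_id", "completed_T3", "website_user"] + ITEM_COLUMNS

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "t": True, "f": False, "yes": True, "no": False,
}


# --- read report ------------------------------------------------------------

@dataclass
class TableReport:
    """Row accounting for one input table."""

    rows_read: int = 0
    rows_kept: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    @property
    def rows_dropped(self) -> int:
        return self.rows_read - self.rows_kept

    def drop(self, reason: str, n: int = 1) -> None:
        if n:
            self.reasons[reason] = self.reasons.get(reason, 0) + int(n)


@dataclass
class ReadReport:
    """Per-table row accounting attached to a freshly read cohort."""

    tables: dict[str, TableReport] = field(default_factory=dict)

    @property
    def total_dropped(self) -> int:
        return sum(t.rows_dropped for t in self.tables.values())

    def to_dict(self) -> dict:
        return {
            name: {
                "rows_read": t.rows_read,
                "rows_kept": t.rows_kept,
                "rows_dropped": t.rows_dropped,
                "reasons": dict(t.reasons),
            }
            for name, t in self.tables.items()
        }


# --- dataset container ------------------------------------------------------

@dataclass
class CohortDataset:
    """The four validated cohort tables.

    ``participants`` anchors referential integrity: every event row in
    ``sessions``, ``messages`` and ``surveys`` refers to a participant_id
    present (and unique) in the registry.
    """

    participants: pd.DataFrame
    sessions: pd.DataFrame
    messages: pd.DataFrame
    surveys: pd.DataFrame
    report: ReadReport | None = None

    def validate(self) -> "CohortDataset":
        pids = self.participants["participant_id"]
        if pids.duplicated().any():
            dups = sorted(pids[pids.duplicated()].unique())
            raise ValueError(f"duplicate participant_id: {dups}")
        known = set(pids)
        for name in ("sessions", "messages", "surveys"):
            frame = getattr(self, name)
            orphan = ~frame["participant_id"].isin(known)
            if orphan.any():
                raise ValueError(
                    f"{name}: {int(orphan.sum())} rows reference unknown participants"
                )
        return self

    def participant_ids(self) -> list[str]:
        return list(self.participants["participant_id"])

    def __eq__(self, other: object) -> bool:  # frame-wise value equality
        if not isinstance(other, CohortDataset):
            return NotImplemented
        for name in ("participants", "sessions", "messages", "surveys"):
            a = getattr(self, name).reset_index(drop=True)
            b = getattr(other, name).reset_index(drop=True)
            if set(a.columns) != set(b.columns):
                return False
            try:
                pd.testing.assert_frame_equal(a, b[list(a.columns)],
                                              check_dtype=False)
            except AssertionError:
                return False
        return True


# --- parsing helpers --------------------------------------------------------

def _exact_float(value) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        return float("nan")


def _parse_bool(series: pd.Series) -> pd.Series:
    return series.astype(str).str.strip().str.lower().map(_BOOL_MAP)


def _apply_schema(frame: pd.DataFrame, canonical: Iterable[str],
                  mapping: Mapping[str, str] | None, table: str) -> pd.DataFrame:
    """Rename file columns to canonical names via ``{canonical: actual}``."""
    if mapping:
        frame = frame.rename(columns={v: k for k, v in mapping.items()})
    missing = [c for c in canonical if c not in frame.columns]
    if missing:
        raise ValueError(f"{table}: missing required columns {missing}")
    return frame[list(canonical)].copy()


def _read_raw(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _drop_rows(frame: pd.DataFrame, bad: pd.Series, reason: str,
               report: TableReport) -> pd.DataFrame:
    n = int(bad.sum())
    if n:
        report.drop(reason, n)
        logger.warning("dropping %d row(s): %s", n, reason)
        frame = frame.loc[~bad]
    return frame


# --- table readers ----------------------------------------------------------

def read_registry(path: str | Path, schema: Mapping[str, str] | None = None,
                  report: TableReport | None = None) -> pd.DataFrame:
    report = report if report is not None else TableReport()
    raw = _apply_schema(_read_raw(path), REGISTRY_COLUMNS, schema, "registry")
    report.rows_read = len(raw)

    out = raw.copy()
    out["participant_id"] = out["participant_id"].str.strip()
    out = _drop_rows(out, out["participant_id"] == "", "empty participant_id", report)
    if out["participant_id"].duplicated().any():
        raise ValueError("registry: duplicate participant_id")

    for col in ("registration_date", "infant_dob", "first_activation_date"):
        out[col] = pd.to_datetime(out[col], errors="coerce", format="ISO8601")
    out = _drop_rows(out, out["registration_date"].isna(), "invalid registration_date", report)
    out = _drop_rows(out, out["infant_dob"].isna(), "invalid infant_dob", report)

    # eligibility: infant no more than 13 weeks old at registration; antenatal
    # registration (expectant parents) is allowed, so no lower bound.
    age_at_reg = (out["registration_date"] - out["infant_dob"]).dt.days
    out = _drop_rows(out, age_at_reg > MAX_REGISTRATION_AGE_DAYS,
                     "registration after infant age 13 weeks", report)
    bad_act = out["first_activation_date"].notna() & (
        out["first_activation_date"] < out["registration_date"])
    out = _drop_rows(out, bad_act, "first_activation_date before registration", report)

    for col, levels in COVARIATE_ENUMS.items():
        vals = out[col].str.strip()
        out[col] = vals
        out = _drop_rows(out, ~vals.reindex(out.index).isin(levels),
                         f"{col}: unknown value", report)
    out["country_of_birth"] = out["country_of_birth"].str.strip()
    for col in COVARIATE_NUMERIC:
        # python float() round-trips repr-written values exactly
        out[col] = out[col].map(_exact_float)

    report.rows_kept = len(out)
    return out.reset_index(drop=True)


def _read_events(path: str | Path, columns: list[str], table: str,
                 schema: Mapping[str, str] | None,
                 report: TableReport) -> pd.DataFrame:
    raw = _apply_schema(_read_raw(path), columns, schema, table)
    report.rows_read = len(raw)
    raw["participant_id"] = raw["participant_id"].str.strip()
    return raw


def read_sessions(path: str | Path, schema: Mapping[str, str] | None = None,
                  report: TableReport | None = None) -> pd.DataFrame:
    report = report if report is not None else TableReport()
    out = _read_events(path, SESSION_COLUMNS, "sessions", schema, report)
    out["start_timestamp"] = pd.to_datetime(out["start_timestamp"],
                                            errors="coerce", format="ISO8601")
    out = _drop_rows(out, out["start_timestamp"].isna(), "invalid timestamp", report)
    pages = pd.to_numeric(out["pages_viewed"], errors="coerce")
    out["pages_viewed"] = pages
    out = _drop_rows(out, ~(pages >= 1), "pages_viewed < 1", report)
    out["pages_viewed"] = out["pages_viewed"].astype(int)
    report.rows_kept = len(out)
    return out.reset_index(drop=True)


def read_messages(path: str | Path, schema: Mapping[str, str] | None = None,
                  report: TableReport | None = None) -> pd.DataFrame:
    report = report if report is not None else TableReport()
    out = _read_events(path, MESSAGE_COLUMNS, "messages", schema, report)
    out["sent_timestamp"] = pd.to_datetime(out["sent_timestamp"],
                                           errors="coerce", format="ISO8601")
    out = _drop_rows(out, out["sent_timestamp"].isna(), "invalid timestamp", report)
    channel = out["channel"].str.strip().str.lower()
    out["channel"] = channel
    out = _drop_rows(out, ~channel.reindex(out.index).isin(CHANNEL_LEVELS),
                     "channel: unknown value", report)
    opened = _parse_bool(out["opened"])
    out["opened"] = opened
    out = _drop_rows(out, opened.reindex(out.index).isna(), "opened: not boolean", report)
    out["opened"] = out["opened"].astype(bool)
    report.rows_kept = len(out)
    return out.reset_index(drop=True)


def read_surveys(path: str | Path, schema: Mapping[str, str] | None = None,
                 report: TableReport | None = None) -> pd.DataFrame:
    report = report if report is not None else TableReport()
    out = _read_events(path, SURVEY_COLUMNS, "surveys", schema, report)
    for col in ("completed_T3", "website_user"):
        vals = _parse_bool(out[col])
        out[col] = vals
        out = _drop_rows(out, vals.reindex(out.index).isna(),
                         f"{col}: not boolean", report)
        out[col] = out[col].astype(bool)
    for col in ITEM_COLUMNS:
        vals = out[col].str.strip().replace("", "NA")
        out[col] = vals
        out = _drop_rows(out, ~vals.reindex(out.index).isin(ITEM_RESPONSES),
                         f"{col}: unknown response", report)
    out = _drop_rows(out, out["participant_id"].duplicated(),
                     "duplicate survey row", report)
    report.rows_kept = len(out)
    return out.reset_index(drop=True)


def read_cohort(registry_path: str | Path, sessions_path: str | Path,
                messages_path: str | Path, survey_path: str | Path,
                schema_config: Mapping[str, Mapping[str, str]] | None = None,
                ) -> CohortDataset:
    """Read and validate the four cohort tables.

    ``schema_config`` optionally maps, per table, canonical column names to
    the actual names in the files, e.g. ``{"sessions": {"participant_id":
    "uid"}}``. Rows violating row-level invariants are dropped and counted in
    the attached :class:`ReadReport`; events referencing unknown participants
    are dropped as orphans. A missing file or a duplicate participant id is
    fatal.
    """
    schema_config = schema_config or {}
    report = ReadReport()
    report.tables["registry"] = reg_rep = TableReport()
    participants = read_registry(registry_path, schema_config.get("registry"), reg_rep)
    known = set(participants["participant_id"])

    frames = {}
    for name, path, reader in (
        ("sessions", sessions_path, read_sessions),
        ("messages", messages_path, read_messages),
        ("surveys", survey_path, read_surveys),
    ):
        report.tables[name] = tab = TableReport()
        frame = reader(path, schema_config.get(name), tab)
        orphan = ~frame["participant_id"].isin(known)
        frame = _drop_rows(frame, orphan, "unknown participant_id", tab)
        tab.rows_kept = len(frame)
        frames[name] = frame.reset_index(drop=True)

    dataset = CohortDataset(participants, frames["sessions"], frames["messages"],
                            frames["surveys"], report=report)
    dataset.validate()
    logger.info("read cohort: %d participants, %d sessions, %d messages, "
                "%d surveys (%d rows dropped)", len(participants),
                len(frames["sessions"]), len(frames["messages"]),
                len(frames["surveys"]), report.total_dropped)
    return dataset


# --- writers ----------------------------------------------------------------

_DATE_COLUMNS = {"registration_date", "infant_dob", "first_activation_date"}
_TIMESTAMP_COLUMNS = {"start_timestamp", "sent_timestamp"}


def write_table(rows: pd.DataFrame, path: str | Path,
                columns: list[str] | None = None) -> Path:
    """Write a result or input table as UTF-8 CSV with a stable column order.

    Dates render as ISO ``YYYY-MM-DD``, timestamps as ``YYYY-MM-DDTHH:MM:SS``
    so that a write/read round trip reproduces values exactly.
    """
    path = Path(path)
    out = rows.copy()
    if columns is not None:
        out = out[list(columns)]
    for col in out.columns:
        if col in _DATE_COLUMNS:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
        elif col in _TIMESTAMP_COLUMNS:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
        elif pd.api.types.is_float_dtype(out[col]):
            # repr gives the shortest digit string that round-trips exactly
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, index=False)
    return path


def write_cohort(dataset: CohortDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the four cohort tables into ``out_dir`` (created if needed)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "registry": write_table(dataset.participants, out_dir / "registry.csv",
                                REGISTRY_COLUMNS),
        "sessions": write_table(dataset.sessions, out_dir / "sessions.csv",
                                SESSION_COLUMNS),
        "messages": write_table(dataset.messages, out_dir / "messages.csv",
                                MESSAGE_COLUMNS),
        "surveys": write_table(dataset.surveys, out_dir / "survey.csv",
                               SURVEY_COLUMNS),
    }
    return paths


def read_cohort_dir(in_dir: str | Path,
                    schema_config: Mapping[str, Mapping[str, str]] | None = None,
                    ) -> CohortDataset:
    """Read a cohort previously written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    return read_cohort(in_dir / "registry.csv", in_dir / "sessions.csv",
                       in_dir / "messages.csv", in_dir / "survey.csv",
                       schema_config)
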