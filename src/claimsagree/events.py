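"""Domain types and I/O for administrative health events.

The unit of analysis is a dated healthcare encounter — a physician billing
claim or a hospitalization — carrying a single diagnosis code.  Asthma
encounters are identified by rubric 493 (ICD-9) for all physician claims and
for hospitalizations up to the end of 2005, and by rubric J45 (ICD-10) for
hospitalizations from 2006 onward, matching the coding-revision switchover in
Quebec hospital abstracts.  Code matching is a three-character prefix match
after stripping punctuation, because only the three-character rubrics define
the phenotype.

Tabular I/O uses delimited text (CSV, or TSV when the file extension is
``.tsv``) with fixed column names.  Missing covariate values are encoded as
empty fields.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventKind",
    "CodeSystem",
    "HealthEvent",
    "Person",
    "SelfReport",
    "EventParseError",
    "CodeEraWarning",
    "read_events",
    "read_persons",
    "read_self_reports",
    "write_events",
    "is_asthma_event",
    "asthma_mask",
    "normalize_events",
    "HOSPITAL_DATA_START",
    "CLAIMS_DATA_START",
    "ICD10_HOSPITAL_START",
]

#: First calendar day with physician-claims coverage.
CLAIMS_DATA_START = date(1983, 1, 1)
#: First calendar day with hospitalization coverage.
HOSPITAL_DATA_START = date(1987, 1, 1)
#: Hospitalizations are coded ICD-10 from this day on, ICD-9 before.
ICD10_HOSPITAL_START = date(2006, 1, 1)

_DATE_MIN = date(1900, 1, 1)
_DATE_MAX = date(2100, 1, 1)

EVENT_COLUMNS = ["person_id", "date", "kind", "code", "code_system"]

#: Covariates collected per participant, all categorical, all possibly missing.
COVARIATE_NAMES = [
    "sex",
    "language",
    "parental_birthplace",
    "area_of_residence",
    "income_quartile",
    "material_deprivation",
    "social_deprivation",
    "maternal_education",
    "paternal_education",
    "parental_asthma",
    "allergy_services",
]


class EventKind(str, enum.Enum):
    physician_claim = "physician_claim"
    hospitalization = "hospitalization"


class CodeSystem(str, enum.Enum):
    ICD9 = "ICD9"
    ICD10 = "ICD10"


class EventParseError(ValueError):
    """Raised when an event file contains malformed rows; names the lines."""


class CodeEraWarning(UserWarning):
    """A diagnosis code appears in the wrong coding-revision era."""


@dataclass(frozen=True)
class HealthEvent:
    """One dated healthcare encounter with a diagnosis code."""

    person_id: str
    date: date
    kind: EventKind
    code: str
    code_system: CodeSystem

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("diagnosis code must be non-empty")
        if not (_DATE_MIN <= self.date <= _DATE_MAX):
            raise ValueError(f"event date {self.date} outside [1900, 2100]")
        if (
            self.kind is EventKind.hospitalization
            and self.date < HOSPITAL_DATA_START
        ):
            warnings.warn(
                f"hospitalization dated {self.date} precedes the "
                f"{HOSPITAL_DATA_START} start of hospital data",
                CodeEraWarning,
                stacklevel=3,
            )


@dataclass
class Person:
    person_id: str
    birth_year: int
    interview_date: date | None = None
    bcg: bool | None = None
    coverage_gaps: list[tuple[date, date]] = field(default_factory=list)
    covariates: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        gaps = sorted(self.coverage_gaps)
        for (a0, a1), (b0, _) in zip(gaps, gaps[1:]):
            if a1 >= b0:
                raise ValueError("coverage gaps must be disjoint intervals")
        self.coverage_gaps = gaps


@dataclass(frozen=True)
class SelfReport:
    """Answers to the two survey items on asthma.

    The physician-diagnosis item is only asked when ever-asthma is answered
    yes, so ``physician_diagnosed`` must be missing or false otherwise.
    """

    person_id: str
    ever_asthma: bool | None
    physician_diagnosed: bool | None

    def __post_init__(self) -> None:
        if self.ever_asthma is not True and self.physician_diagnosed is True:
            raise ValueError(
                "physician_diagnosed=True requires ever_asthma=True (skip logic)"
            )


# ---------------------------------------------------------------------------
# file I/O


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise EventParseError(f"{path}: duplicate header column(s) {dupes}")
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an event table; returns one row per encounter.

    Raises :class:`EventParseError` naming each malformed line (1-based data
    line numbers, header is line 1).
    """
    df = _read_delimited(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise EventParseError(f"{path}: missing column(s) {missing}")
    df = df[EVENT_COLUMNS].copy()

    errors: list[str] = []
    parsed = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    for i in np.flatnonzero(parsed.isna().to_numpy()):
        errors.append(f"line {i + 2}: bad ISO date {df['date'].iat[i]!r}")
    kinds = {k.value for k in EventKind}
    for i in np.flatnonzero(~df["kind"].isin(kinds).to_numpy()):
        errors.append(f"line {i + 2}: invalid kind {df['kind'].iat[i]!r}")
    systems = {s.value for s in CodeSystem}
    for i in np.flatnonzero(~df["code_system"].isin(systems).to_numpy()):
        errors.append(
            f"line {i + 2}: invalid code_system {df['code_system'].iat[i]!r}"
        )
    for i in np.flatnonzero((df["code"].str.len() == 0).to_numpy()):
        errors.append(f"line {i + 2}: empty diagnosis code")
    if errors:
        raise EventParseError(f"{path}: " + "; ".join(errors))

    df["date"] = parsed.dt.normalize()
    return df.reset_index(drop=True)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    out = events.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[EVENT_COLUMNS].to_csv(path, index=False)


def read_persons(path: str | Path) -> pd.DataFrame:
    """Read a person table (person_id, birth_year, interview_date, bcg,
    plus covariate columns; empty field = missing)."""
    df = _read_delimited(path)
    if "person_id" not in df.columns:
        raise EventParseError(f"{path}: missing column person_id")
    if "birth_year" in df.columns:
        df["birth_year"] = pd.to_numeric(df["birth_year"]).astype(int)
    if "interview_date" in df.columns:
        df["interview_date"] = pd.to_datetime(
            df["interview_date"].replace("", pd.NA), format="%Y-%m-%d"
        )
    if "bcg" in df.columns:
        df["bcg"] = df["bcg"].map({"True": True, "False": False, "1": True, "0": False})
    for c in df.columns:
        if df[c].dtype == object:
            df[c] = df[c].replace("", pd.NA)
    return df


def read_self_reports(path: str | Path) -> pd.DataFrame:
    df = _read_delimited(path)
    for c in ("ever_asthma", "physician_diagnosed"):
        if c in df.columns:
            df[c] = df[c].map(
                {"True": True, "False": False, "1": True, "0": False, "": pd.NA}
            )
    bad = df["physician_diagnosed"].eq(True) & ~df["ever_asthma"].eq(True)
    if bad.any():
        raise EventParseError(
            f"{path}: physician_diagnosed=True without ever_asthma=True on "
            f"{int(bad.sum())} row(s) (skip logic violated)"
        )
    return df


# ---------------------------------------------------------------------------
# asthma identification


def _strip_code(code: str) -> str:
    return code.replace(".", "").replace(" ", "").upper()


def is_asthma_event(event: HealthEvent, *, strict_era: bool = False) -> bool:
    """True when the encounter's code identifies asthma under the era rules.

    Physician claims match rubric 493 over the whole study period;
    hospitalizations match 493 (ICD-9) through 2005 and J45 (ICD-10) from
    2006.  A hospitalization coded in the wrong revision for its date raises
    a :class:`CodeEraWarning` (or ``ValueError`` when ``strict_era``).
    """
    code = _strip_code(event.code)
    if event.kind is EventKind.physician_claim:
        if event.code_system is CodeSystem.ICD9:
            return code.startswith("493")
        # ICD-10-coded claims are accepted but flagged: the claims file is
        # documented as ICD-9 throughout.
        if code.startswith("J45"):
            msg = f"ICD-10 physician claim on {event.date}"
            if strict_era:
                raise ValueError(msg)
            warnings.warn(msg, CodeEraWarning, stacklevel=2)
            return True
        return False

    # hospitalization
    icd9_era = event.date < ICD10_HOSPITAL_START
    if event.code_system is CodeSystem.ICD9:
        if not code.startswith("493"):
            return False
        if not icd9_era:
            msg = f"ICD-9 hospitalization code after 2005 ({event.date})"
            if strict_era:
                raise ValueError(msg)
            warnings.warn(msg, CodeEraWarning, stacklevel=2)
        return True
    if not code.startswith("J45"):
        return False
    if icd9_era:
        msg = f"ICD-10 hospitalization code before 2006 ({event.date})"
        if strict_era:
            raise ValueError(msg)
        warnings.warn(msg, CodeEraWarning, stacklevel=2)
    return True


def asthma_mask(events: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`is_asthma_event` over an event table.

    Applies the same prefix rules in warn-accept mode (wrong-era codes
    count, as in the scalar form) without emitting per-row warnings; use the
    scalar form to audit individual encounters.
    """
    code = (
        events["code"]
        .str.replace(".", "", regex=False)
        .str.replace(" ", "", regex=False)
        .str.upper()
    )
    is_claim = events["kind"].eq(EventKind.physician_claim.value)
    is_hosp = events["kind"].eq(EventKind.hospitalization.value)
    icd9 = events["code_system"].eq(CodeSystem.ICD9.value)

    m493 = code.str.startswith("493")
    mj45 = code.str.startswith("J45")
    system_hit = m493 & icd9 | mj45 & ~icd9
    return (is_claim | is_hosp) & system_hit


def normalize_events(events: pd.DataFrame) -> pd.DataFrame:
    """Collapse to at most one encounter per person-day.

    Multiple claims on one day count once; when a claim and a hospitalization
    share a day the hospitalization is retained.  Output is sorted by
    (person_id, date).  Idempotent.
    """
    if len(events) == 0:
        return events.copy()
    hosp_first = events["kind"].eq(EventKind.hospitalization.value)
    out = (
        events.assign(_hosp=hosp_first)
        .sort_values(["person_id", "date", "_hosp"], ascending=[True, True, False])
        .drop_duplicates(subset=["person_id", "date"], keep="first")
        .drop(columns="_hosp")
        .reset_index(drop=True)
    )
    return out


def events_from_records(records: Iterable[HealthEvent]) -> pd.DataFrame:
    """Build an event table from :class:`HealthEvent` instances."""
    rows = [
        (e.person_id, pd.Timestamp(e.date), e.kind.value, e.code, e.code_system.value)
        for e in records
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)
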