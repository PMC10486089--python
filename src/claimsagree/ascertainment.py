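"""Claims-based asthma case definitions and prevalence estimation.

A person is classified as having asthma when, inside a 30-year lookback
window (claims from 1983, hospitalizations from 1987, both until the
interview), they have at least one asthma hospitalization or at least two
asthma physician claims falling within ``k`` years of each other, for
``k`` in {1, 2, 3, 5, 30}.  "Within k years" is a day-difference rule:
two claims qualify when they are at most ``floor(k * 365.25)`` days apart,
which is leap-safe and monotone in ``k``.  Because claim dates are distinct
after normalization, the minimum gap over consecutive sorted dates equals
the minimum over all pairs, so the pair test runs in linear time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd

from .events import CLAIMS_DATA_START, HOSPITAL_DATA_START, EventKind

__all__ = [
    "AlgorithmSpec",
    "AscertainmentResult",
    "WINDOW_YEARS_GRID",
    "window_days",
    "meets_pair_within",
    "classify_person",
    "classify_cohort",
    "prevalence",
    "SAMPLING_DEFINITION",
]

#: The five window lengths (years) compared in the analysis.
WINDOW_YEARS_GRID = (1, 2, 3, 5, 30)


@dataclass(frozen=True)
class AlgorithmSpec:
    """A parametrized claims-ascertainment rule.

    ``lookback_end`` may be None, meaning "per person, the interview date".
    """

    min_claims: int = 2
    window_years: float = 30
    lookback_start: date = CLAIMS_DATA_START
    lookback_end: date | None = None
    hospitalization_sufficient: bool = True

    def __post_init__(self) -> None:
        if self.window_years <= 0:
            raise ValueError("window_years must be positive")
        if self.lookback_end is not None and not (
            self.lookback_start < self.lookback_end
        ):
            raise ValueError("lookback_start must precede lookback_end")

    @property
    def window_days(self) -> int:
        return window_days(self.window_years)


#: The pre-1995 definition used to build the sampling strata: >=2 claims or
#: >=1 hospitalization until the end of 1994, any spacing.
SAMPLING_DEFINITION = AlgorithmSpec(
    window_years=1000, lookback_end=date(1994, 12, 31)
)


def window_days(k_years: float) -> int:
    return math.floor(k_years * 365.25)


@dataclass(frozen=True)
class AscertainmentResult:
    person_id: str
    status: bool
    n_claims: int
    n_hospitalizations: int
    first_service_date: date | None = None
    last_service_date: date | None = None


def meets_pair_within(dates: Sequence, k_years: float) -> bool:
    """True when some pair of claim dates is at most floor(k*365.25) days apart.

    ``dates`` are sorted distinct claim dates inside the lookback; fewer than
    two dates can never satisfy the pair rule.
    """
    if len(dates) < 2:
        return False
    d = pd.to_datetime(pd.Series(list(dates))).sort_values()
    gaps = d.diff().dt.days.dropna().to_numpy()
    return bool(gaps.min() <= window_days(k_years))


def classify_person(
    events: pd.DataFrame, spec: AlgorithmSpec, person_id: str | None = None
) -> AscertainmentResult:
    """Apply one case definition to one person's normalized asthma events."""
    if person_id is None:
        ids = events["person_id"].unique()
        person_id = str(ids[0]) if len(ids) else ""
    ev = events[events["person_id"] == person_id] if len(events) else events
    dates = pd.to_datetime(ev["date"]) if len(ev) else pd.Series(dtype="datetime64[ns]")
    end = pd.Timestamp(spec.lookback_end) if spec.lookback_end else pd.Timestamp.max
    in_window = (dates >= pd.Timestamp(spec.lookback_start)) & (dates <= end)
    ev = ev[in_window]
    dates = dates[in_window]

    is_hosp = ev["kind"].eq(EventKind.hospitalization.value) if len(ev) else pd.Series(dtype=bool)
    n_hosp = int(is_hosp.sum()) if len(ev) else 0
    claim_dates = dates[~is_hosp].sort_values() if len(ev) else dates
    n_claims = len(claim_dates)

    status = bool(
        (spec.hospitalization_sufficient and n_hosp >= 1)
        or (
            n_claims >= spec.min_claims
            and meets_pair_within(claim_dates, spec.window_years)
        )
    )
    first = dates.min().date() if len(dates) else None
    last = dates.max().date() if len(dates) else None
    return AscertainmentResult(person_id, status, n_claims, n_hosp, first, last)


def classify_cohort(
    events: pd.DataFrame,
    persons: pd.DataFrame,
    spec: AlgorithmSpec,
) -> pd.DataFrame:
    """Vectorized case classification for every person in ``persons``.

    ``events`` must already be asthma-filtered and normalized (one encounter
    per person-day).  The lookback closes at each person's interview date
    when ``spec.lookback_end`` is None.  Returns one row per person with
    columns status, n_claims, n_hosp, first_date, last_date.
    """
    ev = events.merge(
        persons[["person_id"]].assign(
            _end=pd.to_datetime(persons["interview_date"])
            if spec.lookback_end is None and "interview_date" in persons
            else pd.Timestamp(spec.lookback_end or date(2100, 1, 1))
        ),
        on="person_id",
        how="inner",
    )
    dates = pd.to_datetime(ev["date"])
    keep = (dates >= pd.Timestamp(spec.lookback_start)) & (dates <= ev["_end"])
    ev = ev[keep].copy()
    ev["date"] = pd.to_datetime(ev["date"])

    is_hosp = ev["kind"].eq(EventKind.hospitalization.value)
    hosp_counts = ev[is_hosp].groupby("person_id").size()

    claims = ev[~is_hosp].sort_values(["person_id", "date"])
    gaps = claims.groupby("person_id")["date"].diff().dt.days
    min_gap = gaps.groupby(claims["person_id"]).min()
    claim_counts = claims.groupby("person_id").size()

    svc = ev.groupby("person_id")["date"].agg(["min", "max"])

    out = persons[["person_id"]].copy()
    out["n_claims"] = out["person_id"].map(claim_counts).fillna(0).astype(int)
    out["n_hosp"] = out["person_id"].map(hosp_counts).fillna(0).astype(int)
    pair_ok = out["person_id"].map(min_gap) <= spec.window_days
    out["status"] = (
        (spec.hospitalization_sufficient & (out["n_hosp"] >= 1))
        | ((out["n_claims"] >= spec.min_claims) & pair_ok.fillna(False))
    )
    out["first_date"] = out["person_id"].map(svc["min"])
    out["last_date"] = out["person_id"].map(svc["max"])
    return out


def prevalence(
    status: Sequence[bool] | pd.Series,
    weights: Sequence[float] | pd.Series | None = None,
) -> dict[str, float]:
    """Crude and design-corrected prevalence of a binary status.

    crude = 100 * n_cases / n_valid; corrected = 100 * sum(w*status)/sum(w).
    With unit (or no) weights the two coincide.
    """
    s = np.asarray(status, dtype=float)
    s = s[~np.isnan(s)]
    n_valid = s.size
    if n_valid == 0:
        raise ValueError("prevalence undefined: no valid statuses")
    n_cases = int(s.sum())
    crude = 100.0 * n_cases / n_valid
    if weights is None:
        corrected = crude
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        if w.size != np.asarray(status).size:
            raise ValueError("weights must align with status")
        sv = np.asarray(status, dtype=float)
        ok = ~np.isnan(sv)
        corrected = 100.0 * float(np.sum(w[ok] * sv[ok])) / float(np.sum(w[ok]))
    return {
        "crude_pct": crude,
        "corrected_pct": corrected,
        "n_cases": n_cases,
        "n_valid": n_valid,
    }
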