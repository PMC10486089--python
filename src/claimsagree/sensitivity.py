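"""Scenario and stratified sensitivity analyses for the agreement estimates.

Three analyses probe the robustness of the weighted agreement statistics:

1.  *Re-inclusion scenarios.*  The survey frame excluded persons who were
    negative under the pre-1995 sampling definition but had a single asthma
    claim before 1995 — about 5.9% of eligible non-asthma persons.  The
    scenario re-introduces that many hypothetical participants (allocated
    proportionally across the two non-asthma strata) with administrative
    status "no", assumes a fraction of them self-report asthma (1.0 in the
    worst case, 0.5 in the intermediate case), and recomputes kappa.

2.  *Coverage-gap exclusion.*  Persons with any interruption of provincial
    health-insurance coverage during the checkable 1983-1994 period are
    removed and the agreement statistics recomputed.

3.  *Stratified agreement.*  Among persons with at least one asthma service
    who are positive by either source, percent agreement is tabulated by age
    at first service, age at last service, service-span duration and
    hospitalization history.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .agreement import AgreementTable, EstimateCI, cohen_kappa
from .design import DesignWeights

__all__ = [
    "ScenarioSpec",
    "reinclusion_scenario",
    "exclude_coverage_gaps",
    "stratified_agreement",
    "STRATIFIERS",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One re-inclusion scenario for the excluded single-claim persons."""

    excluded_fraction: float = 0.059
    report_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.excluded_fraction < 1:
            raise ValueError("excluded_fraction must lie in [0, 1)")
        if not 0 <= self.report_fraction <= 1:
            raise ValueError("report_fraction must lie in [0, 1]")


def reinclusion_scenario(
    table: AgreementTable,
    design: DesignWeights,
    scenario: ScenarioSpec,
    *,
    total_weight: float | None = None,
) -> EstimateCI:
    """Kappa after hypothetically re-including the excluded persons.

    The number of re-included persons is ``excluded_fraction /
    (1 - excluded_fraction)`` times the surveyed non-asthma-stratum count,
    rounded to whole persons and allocated proportionally across the two
    non-asthma strata.  All are administrative negatives;
    ``report_fraction`` of them self-report asthma (cell c), the rest do not
    (cell d).  ``total_weight`` is the weighted mass behind the baseline
    table (defaults to the design's cohort size, the sum of all weights).
    """
    non_asthma = design.table[design.table.index.str.contains("Asthma-")]
    if non_asthma.empty:
        raise ValueError("design has no non-asthma strata")
    n_non = int(non_asthma["n_survey"].sum())
    m_add = round(scenario.excluded_fraction / (1 - scenario.excluded_fraction) * n_non)
    if m_add == 0:
        return cohen_kappa(table)

    W0 = float(total_weight) if total_weight is not None else float(design.cohort_size)
    # proportional allocation over the two non-asthma strata
    alloc = non_asthma["n_survey"] / n_non
    added_w = 0.0
    for stratum, frac in alloc.items():
        added_w += m_add * float(frac) * design.weight_of(stratum)
    n_yes = round(scenario.report_fraction * m_add)
    n_no = m_add - n_yes
    w_yes = added_w * (n_yes / m_add)
    w_no = added_w - w_yes

    Wn = W0 + added_w
    p = np.array([table.p_a, table.p_b, table.p_c, table.p_d]) * W0
    p[2] += w_yes
    p[3] += w_no
    p = p / Wn
    new = AgreementTable(
        table.a, table.b, table.c + n_yes, table.d + n_no,
        *p, table.n_actual + m_add,
    )
    return cohen_kappa(new)


def _parse_gaps(spec: str) -> list[tuple[np.datetime64, np.datetime64]]:
    out = []
    if not spec or pd.isna(spec):
        return out
    for part in str(spec).split(";"):
        a, b = part.split("/")
        out.append((np.datetime64(a), np.datetime64(b)))
    return out


def exclude_coverage_gaps(
    persons: pd.DataFrame,
    events: pd.DataFrame,
    period: tuple[date, date] = (date(1983, 1, 1), date(1994, 12, 31)),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop persons with any insurance-coverage gap intersecting ``period``.

    Gap intervals live in the persons table's ``coverage_gaps`` column as
    ``start/end`` pairs joined by ``;`` (empty = none).  Returns the filtered
    (persons, events) pair; downstream statistics are then recomputed.
    """
    lo, hi = np.datetime64(period[0].isoformat()), np.datetime64(period[1].isoformat())

    def has_gap(spec) -> bool:
        return any(a <= hi and b >= lo for a, b in _parse_gaps(spec))

    flagged = persons["coverage_gaps"].map(has_gap) if "coverage_gaps" in persons else pd.Series(False, index=persons.index)
    kept = persons[~flagged.astype(bool)]
    kept_ids = set(kept["person_id"])
    return (
        kept.reset_index(drop=True),
        events[events["person_id"].isin(kept_ids)].reset_index(drop=True),
    )


#: Recognized stratifiers and their bin edges (closed on integer ages/years).
STRATIFIERS = {
    "age_at_first": [(8, 11), (12, 17), (18, None)],
    "age_at_last": [(8, 11), (12, 17), (18, None)],
    "duration": [(0, 5), (6, 10), (11, 20), (21, None)],
    "any_hospitalization": None,
}


def _bin_label(lo: int, hi: int | None, unit: str = "") -> str:
    return f">={lo}{unit}" if hi is None else f"{lo}-{hi}{unit}"


def stratified_agreement(
    records: pd.DataFrame,
    stratifier: str,
    weights=None,
) -> pd.Series:
    """Percent agreement per bin of an asthma-history stratifier.

    ``records`` holds one row per person of the analysis subset (at least one
    asthma service and positive by either source) with columns ``agree``
    (bool) and the stratifier inputs ``age_at_first``, ``age_at_last``,
    ``duration_years``, ``any_hospitalization``.  Empty bins are reported as
    NaN, not 0%.  When ``weights`` is given the percent is design-weighted.
    """
    if stratifier not in STRATIFIERS:
        raise ValueError(f"unknown stratifier {stratifier!r}")
    w = (
        np.ones(len(records))
        if weights is None
        else np.asarray(weights, dtype=float)
    )
    agree = records["agree"].astype(bool).to_numpy()

    if stratifier == "any_hospitalization":
        groups = {
            "yes": records["any_hospitalization"].astype(bool).to_numpy(),
            "no": ~records["any_hospitalization"].astype(bool).to_numpy(),
        }
    else:
        col = "duration_years" if stratifier == "duration" else stratifier
        vals = np.floor(records[col].astype(float).to_numpy()).astype(int)
        groups = {}
        for lo, hi in STRATIFIERS[stratifier]:
            mask = vals >= lo if hi is None else (vals >= lo) & (vals <= hi)
            groups[_bin_label(lo, hi)] = mask

    out = {}
    for label, mask in groups.items():
        tot = float(w[mask].sum())
        out[label] = 100.0 * float(w[mask & agree].sum()) / tot if tot > 0 else np.nan
    return pd.Series(out, name=f"pct_agreement_by_{stratifier}")
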