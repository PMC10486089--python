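"""Stratum assignment and inverse-probability weights for the balanced design.

The survey drew near-equal numbers from four strata formed by crossing BCG
vaccination (yes/no) with childhood asthma status under the pre-1995 claims
definition.  The sampling probability in stratum *s* is
``n_survey_s / n_cohort_s`` and each participant's design weight is its
inverse, so weights sum to the cohort size.  Weights are deliberately not
normalized: confidence intervals downstream use the actual number of survey
respondents as the effective sample size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["STRATA", "DesignWeights", "assign_stratum", "compute_weights"]

STRATA = ("BCG+/Asthma+", "BCG+/Asthma-", "BCG-/Asthma+", "BCG-/Asthma-")


def assign_stratum(bcg: bool | None, childhood_asthma: bool | None) -> str:
    """Label one of the four design strata from the two sampling variables."""
    if bcg is None or childhood_asthma is None or bcg is pd.NA or childhood_asthma is pd.NA:
        raise ValueError("stratum assignment requires both bcg and childhood_asthma")
    return f"BCG{'+' if bcg else '-'}/Asthma{'+' if childhood_asthma else '-'}"


@dataclass(frozen=True)
class DesignWeights:
    """Per-stratum cohort counts, survey counts and inverse-probability weights."""

    table: pd.DataFrame  # index: stratum; columns: n_cohort, n_survey, weight

    def weight_of(self, stratum: str) -> float:
        return float(self.table.loc[stratum, "weight"])

    def person_weights(self, strata: pd.Series) -> pd.Series:
        """Attach per-person weights by stratum membership."""
        return strata.map(self.table["weight"]).astype(float)

    @property
    def cohort_size(self) -> int:
        return int(self.table["n_cohort"].sum())

    def to_frame(self) -> pd.DataFrame:
        return self.table.reset_index().rename(columns={"index": "stratum"})


def compute_weights(
    cohort_counts: Mapping[str, int], survey_counts: Mapping[str, int]
) -> DesignWeights:
    """weight_s = n_cohort_s / n_survey_s for each of the four strata."""
    rows = []
    for s in sorted(set(cohort_counts) | set(survey_counts)):
        nc = int(cohort_counts.get(s, 0))
        ns = int(survey_counts.get(s, 0))
        if ns < 1:
            raise ValueError(f"stratum {s!r}: survey count must be >= 1")
        if ns > nc:
            raise ValueError(
                f"stratum {s!r}: survey count {ns} exceeds cohort count {nc}"
            )
        rows.append((s, nc, ns, nc / ns))
    table = pd.DataFrame(
        rows, columns=["stratum", "n_cohort", "n_survey", "weight"]
    ).set_index("stratum")
    return DesignWeights(table)


def read_design(path) -> DesignWeights:
    """Read a design table (stratum,n_cohort,n_survey[,weight]); the weight
    column, if present, is checked against the recomputed value."""
    df = pd.read_csv(path)
    dw = compute_weights(
        df.set_index("stratum")["n_cohort"].to_dict(),
        df.set_index("stratum")["n_survey"].to_dict(),
    )
    if "weight" in df.columns:
        got = df.set_index("stratum")["weight"].astype(float)
        want = dw.table["weight"]
        if not np.allclose(got.reindex(want.index), want, rtol=1e-6):
            raise ValueError(f"{path}: stored weights disagree with n_cohort/n_survey")
    return dw
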