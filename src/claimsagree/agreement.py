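"""Design-weighted 2x2 agreement statistics with 95% confidence intervals.

Given person-level asthma status from administrative data and from
self-report, the cross-classification

====================  ===========  ===========
cell                  self +       self -
====================  ===========  ===========
admin +               a            b
admin -               c            d
====================  ===========  ===========

yields, on design-weighted cell proportions p_a..p_d:

* overall agreement        p_o   = p_a + p_d
* chance agreement         p_e   = (p_a+p_b)(p_a+p_c) + (p_c+p_d)(p_b+p_d)
* Cohen's kappa            kappa = (p_o - p_e) / (1 - p_e)
* positive agreement       Ppos  = 2 p_a / (2 p_a + p_b + p_c)
* negative agreement       Pneg  = 2 p_d / (2 p_d + p_b + p_c)

Variance estimates use the weighted proportions with the actual number of
contributing respondents as the effective sample size (the survey's stated
convention, since weights are not scaled to the sample).  The kappa interval
uses the Fleiss-Cohen-Everitt large-sample variance; agreement proportions
use the binomial normal approximation; a person-level bootstrap is available
for Ppos/Pneg, whose closed-form standard error is a convention rather than a
derived result.  Intervals are clipped to their valid ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AgreementTable",
    "EstimateCI",
    "build_table",
    "table_from_cells",
    "overall_agreement",
    "cohen_kappa",
    "pos_neg_agreement",
    "kappa_band",
]

_Z = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class EstimateCI:
    estimate: float
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (self.lower <= self.estimate <= self.upper):
            raise ValueError("CI must bracket the estimate")

    def __iter__(self):
        yield from (self.estimate, self.lower, self.upper)


@dataclass(frozen=True)
class AgreementTable:
    """Raw counts and weighted proportions of a 2x2 source comparison."""

    a: int  # admin+/self+
    b: int  # admin+/self-
    c: int  # admin-/self+
    d: int  # admin-/self-
    p_a: float
    p_b: float
    p_c: float
    p_d: float
    n_actual: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")
        if self.a + self.b + self.c + self.d != self.n_actual:
            raise ValueError("cell counts must sum to n_actual")
        total = self.p_a + self.p_b + self.p_c + self.p_d
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weighted proportions sum to {total}, not 1")

    @property
    def proportions(self) -> np.ndarray:
        return np.array([[self.p_a, self.p_b], [self.p_c, self.p_d]])

    def transpose(self) -> "AgreementTable":
        """Swap the roles of the two sources (b <-> c)."""
        return AgreementTable(
            self.a, self.c, self.b, self.d,
            self.p_a, self.p_c, self.p_b, self.p_d, self.n_actual,
        )


def build_table(
    admin_status,
    self_status,
    weights=None,
) -> AgreementTable:
    """Cross-classify two aligned person-level binary vectors.

    Persons with a missing self-report are dropped pairwise; administrative
    status is complete by construction.  ``weights`` default to 1.
    """
    admin = pd.Series(admin_status).reset_index(drop=True)
    self_ = pd.Series(self_status).reset_index(drop=True)
    if len(admin) != len(self_):
        raise ValueError("status vectors must align")
    w = (
        pd.Series(np.ones(len(admin)))
        if weights is None
        else pd.Series(weights).reset_index(drop=True).astype(float)
    )
    keep = self_.notna().to_numpy()
    admin, self_, w = admin[keep], self_[keep], w[keep]
    n = int(keep.sum())
    if n == 0:
        raise ValueError("no overlapping persons with observed self-report")

    adm = admin.astype(bool).to_numpy()
    slf = self_.astype(bool).to_numpy()
    wv = w.to_numpy()
    cells = {
        "a": adm & slf,
        "b": adm & ~slf,
        "c": ~adm & slf,
        "d": ~adm & ~slf,
    }
    counts = {k: int(v.sum()) for k, v in cells.items()}
    wt = float(wv.sum())
    props = {k: float(wv[v].sum()) / wt for k, v in cells.items()}
    return AgreementTable(
        counts["a"], counts["b"], counts["c"], counts["d"],
        props["a"], props["b"], props["c"], props["d"], n,
    )


def table_from_cells(a: int, b: int, c: int, d: int) -> AgreementTable:
    """Unit-weight table from four raw cell counts."""
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    return AgreementTable(a, b, c, d, a / n, b / n, c / n, d / n, n)


def _clip_ci(est: float, lo: float, hi: float, lower_bound: float, upper_bound: float) -> EstimateCI:
    return EstimateCI(
        float(np.clip(est, lower_bound, upper_bound)),
        float(np.clip(lo, lower_bound, upper_bound)),
        float(np.clip(hi, lower_bound, upper_bound)),
    )


def overall_agreement(table: AgreementTable) -> EstimateCI:
    """Proportion of overall agreement p_a + p_d with a binomial-style CI."""
    if table.n_actual == 0:
        raise ValueError("empty table")
    p = table.p_a + table.p_d
    se = np.sqrt(max(p * (1 - p), 0.0) / table.n_actual)
    return _clip_ci(p, p - _Z * se, p + _Z * se, 0.0, 1.0)


def cohen_kappa(table: AgreementTable) -> EstimateCI:
    """Chance-corrected agreement on the weighted proportions.

    The variance is the Fleiss-Cohen-Everitt large-sample form evaluated at
    the weighted cell proportions with n_actual respondents.
    """
    p = table.proportions
    po = p[0, 0] + p[1, 1]
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    pe = float(row @ col)
    if abs(1 - pe) < 1e-12:
        raise ValueError("kappa undefined: degenerate margins (p_e = 1)")
    kappa = (po - pe) / (1 - pe)

    # Fleiss, Cohen & Everitt large-sample variance of kappa-hat
    diag = sum(
        p[i, i] * (1 - (row[i] + col[i]) * (1 - kappa)) ** 2 for i in range(2)
    )
    off = sum(
        p[i, j] * (col[i] + row[j]) ** 2
        for i in range(2)
        for j in range(2)
        if i != j
    ) * (1 - kappa) ** 2
    corr = (kappa - pe * (1 - kappa)) ** 2
    var = (diag + off - corr) / (table.n_actual * (1 - pe) ** 2)
    se = np.sqrt(max(var, 0.0))
    return _clip_ci(kappa, kappa - _Z * se, kappa + _Z * se, -1.0, 1.0)


def pos_neg_agreement(
    table: AgreementTable,
    *,
    method: str = "normal",
    bootstrap_samples: int = 1000,
    seed: int | None = None,
) -> dict[str, EstimateCI]:
    """Proportions of positive and negative agreement.

    Ppos = 2 p_a / (2 p_a + p_b + p_c); Pneg = 2 p_d / (2 p_d + p_b + p_c).
    ``method="normal"`` uses sqrt(P(1-P)/n_actual) as the standard error, the
    same convention as the overall-agreement interval; ``method="bootstrap"``
    resamples persons (multinomially over the weighted cells) instead.
    """
    num_pos = 2 * table.p_a
    num_neg = 2 * table.p_d
    den_pos = num_pos + table.p_b + table.p_c
    den_neg = num_neg + table.p_b + table.p_c
    out: dict[str, EstimateCI] = {}
    for name, num, den in (("Ppos", num_pos, den_pos), ("Pneg", num_neg, den_neg)):
        if den == 0:
            raise ValueError(f"{name} undefined: zero denominator")
        est = num / den
        if method == "normal":
            se = np.sqrt(max(est * (1 - est), 0.0) / table.n_actual)
            out[name] = _clip_ci(est, est - _Z * se, est + _Z * se, 0.0, 1.0)
        elif method == "bootstrap":
            rng = np.random.default_rng(seed)
            probs = np.array([table.p_a, table.p_b, table.p_c, table.p_d])
            draws = rng.multinomial(table.n_actual, probs, size=bootstrap_samples)
            with np.errstate(invalid="ignore", divide="ignore"):
                if name == "Ppos":
                    stats = 2 * draws[:, 0] / (2 * draws[:, 0] + draws[:, 1] + draws[:, 2])
                else:
                    stats = 2 * draws[:, 3] / (2 * draws[:, 3] + draws[:, 1] + draws[:, 2])
            stats = stats[np.isfinite(stats)]
            lo, hi = np.percentile(stats, [2.5, 97.5])
            out[name] = _clip_ci(est, min(lo, est), max(hi, est), 0.0, 1.0)
        else:
            raise ValueError(f"unknown CI method {method!r}")
    return out


#: Interpretation bands for kappa, lower edge inclusive.
_KAPPA_BANDS = [
    (0.80, "very good"),
    (0.60, "good"),
    (0.40, "moderate"),
    (0.20, "fair"),
    (-1.0, "poor"),
]


def kappa_band(kappa: float) -> str:
    """Qualitative label: poor < 0.20 <= fair < 0.40 <= moderate < 0.60 <=
    good < 0.80 <= very good."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [-1, 1]")
    for edge, label in _KAPPA_BANDS:
        if kappa >= edge:
            return label
    return "poor"
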