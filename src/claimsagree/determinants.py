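"""Determinants of agreement: survey-weighted logistic regression.

The outcome is binary agreement between the 30-year administrative asthma
definition and self-reported physician-diagnosed asthma.  Models are fitted
by maximizing the weighted log-likelihood (iteratively reweighted least
squares), with a Taylor-linearization (sandwich) covariance

    cov(beta) = B^-1 M B^-1,

where B is the weighted Fisher information X' diag(w p(1-p)) X and M is the
outer-product sum of per-person weighted score contributions
w_i x_i (y_i - p_i).  With equal weights and a correctly specified model this
reduces to the usual model-based covariance in expectation.  Rescaling all
weights by a constant leaves beta unchanged.

Variable selection follows the purposeful-selection procedure: candidates
whose univariable multi-degree Wald p-value is below 0.25 enter the initial
multivariable model, and those still below 0.25 there are retained in the
final model.

Missing categorical covariates are multiply imputed by weighted multinomial
draws conditional on (outcome, sampling stratum) — all covariates here are
categorical, so cell-conditional draws preserve the outcome association
without a chained-equations dependency — and the per-imputation fits are
pooled by Rubin's rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignMatrix",
    "ModelFit",
    "SelectionTrace",
    "agreement_outcome",
    "build_design",
    "fit_weighted_logistic",
    "univariable_pvalue",
    "purposeful_selection",
    "impute_categoricals",
    "impute_and_pool",
    "rubin_pool",
]

_Z = 1.959963984540054


def agreement_outcome(admin_status, physician_diagnosed) -> pd.Series:
    """1 when the two sources concur (both yes or both no), NA when the
    self-report is missing (those persons are excluded downstream)."""
    adm = pd.Series(admin_status).reset_index(drop=True)
    slf = pd.Series(physician_diagnosed).reset_index(drop=True)
    out = pd.Series(pd.NA, index=adm.index, dtype="object")
    obs = slf.notna()
    out[obs] = adm[obs].astype(bool).to_numpy() == slf[obs].astype(bool).to_numpy()
    return out


@dataclass
class DesignMatrix:
    """Reference-coded design matrix with a term -> column-index map."""

    X: np.ndarray
    columns: list[str]
    terms: dict[str, list[int]]  # variable -> indices of its dummy columns


def build_design(
    data: pd.DataFrame,
    variables: list[str],
    reference: dict[str, str] | None = None,
) -> DesignMatrix:
    """Dummy-code categorical ``variables`` with an intercept.

    ``reference`` maps a variable to its baseline level; default is the most
    frequent level, so odds ratios read against the modal category unless a
    baseline is declared.
    """
    reference = reference or {}
    cols: list[np.ndarray] = [np.ones(len(data))]
    names = ["Intercept"]
    terms: dict[str, list[int]] = {}
    for var in variables:
        s = data[var].astype("object")
        if s.isna().any():
            raise ValueError(f"variable {var!r} has missing values; impute first")
        levels = sorted(map(str, s.unique()))
        ref = reference.get(var, s.mode().iloc[0])
        ref = str(ref)
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not found for {var!r}")
        idx = []
        for lev in levels:
            if lev == ref:
                continue
            idx.append(len(names))
            names.append(f"{var}[{lev}]")
            cols.append((s.astype(str) == lev).to_numpy(float))
        terms[var] = idx
    X = np.column_stack(cols)
    return DesignMatrix(X, names, terms)


@dataclass
class ModelFit:
    params: pd.Series  # beta, indexed by column name
    cov: pd.DataFrame  # sandwich covariance
    terms: dict[str, list[int]]
    n: int
    converged: bool = True

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    def odds_ratios(self) -> pd.DataFrame:
        """Per-term OR with 95% CI: exp(beta), exp(beta +/- 1.96 SE)."""
        se = self.se
        return pd.DataFrame(
            {
                "OR": np.exp(self.params),
                "lower": np.exp(self.params - _Z * se),
                "upper": np.exp(self.params + _Z * se),
            }
        ).drop(index="Intercept", errors="ignore")

    def wald_test(self, variable: str) -> float:
        """Multi-degree-of-freedom Wald p-value for all of a variable's
        dummy columns jointly, on the sandwich covariance."""
        idx = self.terms[variable]
        if not idx:
            return float("nan")
        b = self.params.to_numpy()[idx]
        V = self.cov.to_numpy()[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(V, b))
        return float(stats.chi2.sf(stat, df=len(idx)))


class SeparationError(RuntimeError):
    """IRLS diverged; quasi-complete separation in some covariate."""


def fit_weighted_logistic(
    X: np.ndarray | DesignMatrix,
    y,
    weights=None,
    *,
    columns: list[str] | None = None,
    terms: dict[str, list[int]] | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> ModelFit:
    """Weighted logistic regression with linearized (sandwich) variance.

    Solves the weighted score equations X' (w * (y - p)) = 0 by IRLS until
    the gradient's max-norm falls below ``tol`` (or ``max_iter`` sweeps).
    """
    if isinstance(X, DesignMatrix):
        columns = X.columns
        terms = X.terms
        X = X.X
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if columns is None:
        columns = [f"x{j}" for j in range(k)]

    rank = np.linalg.matrix_rank(X)
    if rank < k:
        _, R = np.linalg.qr(X)
        aliased = [columns[j] for j in range(k) if abs(R[j, j]) < 1e-8]
        raise np.linalg.LinAlgError(f"rank-deficient design; aliased columns: {aliased}")

    beta = np.zeros(k)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        grad = X.T @ (w * (y - p))
        if np.max(np.abs(grad)) < tol * max(1.0, w.sum()):
            converged = True
            break
        info = (X * (w * p * (1 - p))[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        beta = beta + step
        if np.max(np.abs(beta)) > 1e3:
            j = int(np.argmax(np.abs(beta)))
            raise SeparationError(
                f"divergent coefficient for {columns[j]!r}; separation suspected"
            )
    else:
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))

    if np.max(np.abs(beta[1:] if k > 1 else beta)) > 25:
        j = int(np.argmax(np.abs(beta)))
        raise SeparationError(
            f"divergent coefficient for {columns[j]!r}; separation suspected"
        )

    info = (X * (w * p * (1 - p))[:, None]).T @ X
    score = X * (w * (y - p))[:, None]  # per-person weighted score contributions
    M = score.T @ score
    Binv = np.linalg.inv(info)
    cov = Binv @ M @ Binv
    cov = (cov + cov.T) / 2

    return ModelFit(
        params=pd.Series(beta, index=columns),
        cov=pd.DataFrame(cov, index=columns, columns=columns),
        terms=terms or {},
        n=n,
        converged=converged,
    )


def univariable_pvalue(
    data: pd.DataFrame,
    variable: str,
    outcome,
    weights=None,
    reference: dict[str, str] | None = None,
) -> float:
    """Multi-df Wald p-value of one candidate fitted alone (complete cases)."""
    y = pd.Series(outcome).reset_index(drop=True)
    d = data.reset_index(drop=True)
    w = None if weights is None else pd.Series(weights).reset_index(drop=True)
    keep = d[variable].notna() & y.notna()
    dm = build_design(d[keep], [variable], reference)
    fit = fit_weighted_logistic(
        dm, y[keep].astype(float), None if w is None else w[keep]
    )
    return fit.wald_test(variable)


@dataclass
class SelectionTrace:
    univariable_p: dict[str, float]
    entered: list[str]
    multivariable_p: dict[str, float] = field(default_factory=dict)
    retained: list[str] = field(default_factory=list)


def purposeful_selection(
    candidates: list[str],
    data: pd.DataFrame,
    outcome,
    weights=None,
    *,
    threshold: float = 0.25,
    strict: bool = True,
    reference: dict[str, str] | None = None,
) -> tuple[SelectionTrace, ModelFit]:
    """Staged variable selection against a liberal Wald threshold.

    Stage 1 screens univariable p-values; stage 2 fits all entrants jointly;
    stage 3 refits with only the variables whose multivariable p-value still
    clears the threshold.  ``strict`` compares with ``<`` (default) rather
    than ``<=``.  Complete-case within each fit.
    """
    y = pd.Series(outcome).reset_index(drop=True)
    d = data.reset_index(drop=True)
    w = None if weights is None else pd.Series(weights).reset_index(drop=True)
    passes = (lambda p: p < threshold) if strict else (lambda p: p <= threshold)

    uni = {
        v: univariable_pvalue(d, v, y, w, reference) for v in candidates
    }
    entered = [v for v in candidates if passes(uni[v])]
    trace = SelectionTrace(univariable_p=uni, entered=entered)

    def _joint_fit(variables: list[str]) -> ModelFit:
        keep = y.notna()
        for v in variables:
            keep &= d[v].notna()
        dm = build_design(d[keep], variables, reference)
        return fit_weighted_logistic(
            dm, y[keep].astype(float), None if w is None else w[keep]
        )

    if not entered:
        keep = y.notna()
        X = np.ones((int(keep.sum()), 1))
        final = fit_weighted_logistic(
            X, y[keep].astype(float), None if w is None else w[keep],
            columns=["Intercept"],
        )
        return trace, final

    initial = _joint_fit(entered)
    trace.multivariable_p = {v: initial.wald_test(v) for v in entered}
    trace.retained = [v for v in entered if passes(trace.multivariable_p[v])]
    final = _joint_fit(trace.retained) if trace.retained else initial
    return trace, final


# ---------------------------------------------------------------------------
# multiple imputation


def impute_categoricals(
    data: pd.DataFrame,
    variables: list[str],
    outcome,
    strata=None,
    weights=None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One completed dataset: draw each missing categorical from the weighted
    observed distribution of its (outcome, stratum) cell.

    Cells with no observed donor fall back to the outcome margin, then to the
    overall margin.
    """
    rng = rng or np.random.default_rng()
    d = data.reset_index(drop=True).copy()
    y = pd.Series(outcome).reset_index(drop=True)
    s = (
        pd.Series(["_all"] * len(d))
        if strata is None
        else pd.Series(strata).reset_index(drop=True)
    )
    w = (
        pd.Series(np.ones(len(d)))
        if weights is None
        else pd.Series(weights).reset_index(drop=True).astype(float)
    )
    for var in variables:
        col = d[var]
        if col.notna().all():
            continue
        if col.isna().all():
            raise ValueError(f"variable {var!r} is 100% missing; cannot impute")
        obs = col.notna()
        for i in np.flatnonzero((~obs).to_numpy()):
            for cell in (
                obs & y.eq(y.iat[i]) & s.eq(s.iat[i]),
                obs & y.eq(y.iat[i]),
                obs,
            ):
                if cell.any():
                    break
            levels = col[cell].astype(str)
            probs = w[cell].groupby(levels.to_numpy()).sum()
            probs = probs / probs.sum()
            d.iloc[i, d.columns.get_loc(var)] = rng.choice(
                probs.index.to_numpy(), p=probs.to_numpy()
            )
    return d


def rubin_pool(fits: list[ModelFit]) -> ModelFit:
    """Rubin's rules: pooled beta = mean; pooled variance = within-mean +
    (1 + 1/m) * between-imputation variance."""
    if not fits:
        raise ValueError("no fits to pool")
    m = len(fits)
    index = fits[0].params.index
    B = np.stack([f.params.to_numpy() for f in fits])
    W = np.stack([f.cov.to_numpy() for f in fits]).mean(axis=0)
    beta = B.mean(axis=0)
    if m > 1:
        dev = B - beta
        Bcov = dev.T @ dev / (m - 1)
        T = W + (1 + 1 / m) * Bcov
    else:
        T = W
    return ModelFit(
        params=pd.Series(beta, index=index),
        cov=pd.DataFrame(T, index=index, columns=index),
        terms=fits[0].terms,
        n=fits[0].n,
    )


def impute_and_pool(
    data: pd.DataFrame,
    variables: list[str],
    outcome,
    weights=None,
    strata=None,
    *,
    m: int = 20,
    seed: int | None = None,
    reference: dict[str, str] | None = None,
) -> ModelFit:
    """Fit the model on ``m`` multiply-imputed datasets and pool by Rubin's
    rules.  With no missing values every imputation is the observed data and
    the pooled fit equals the single complete-data fit."""
    rng = np.random.default_rng(seed)
    y = pd.Series(outcome).reset_index(drop=True)
    d = data.reset_index(drop=True)
    w = None if weights is None else pd.Series(weights).reset_index(drop=True)
    keep = y.notna()
    d, y = d[keep].reset_index(drop=True), y[keep].reset_index(drop=True)
    s = None if strata is None else pd.Series(strata).reset_index(drop=True)[keep].reset_index(drop=True)
    if w is not None:
        w = w[keep].reset_index(drop=True)

    fits = []
    for _ in range(m):
        completed = impute_categoricals(d, variables, y, s, w, rng)
        dm = build_design(completed, variables, reference)
        fits.append(fit_weighted_logistic(dm, y.astype(float), w))
    return rubin_pool(fits)
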