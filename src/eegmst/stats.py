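"""Group statistics: covariate-adjusted comparisons, correlations,
multiple-testing control and multivariate regression.

Group differences are tested with ANCOVA realised as ordinary least
squares on a group indicator plus covariates; the group F comes from the
residual-sum-of-squares increase when the indicator is dropped, and the
effect size is partial eta squared, SS_group / (SS_group + SS_error).
With a single two-level factor and covariates always retained, Type
I/II/III sums of squares coincide for the group term. Network metrics
are log-transformed, ln(x + 1e-24), before modelling to stabilise their
distributions; the tiny offset only guards exact zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

LOG_OFFSET = 1e-24

#: Fixed significance rule for correlation tests.
CORRELATION_ALPHA = 0.01


@dataclass
class GroupEffect:
    """Covariate-adjusted group comparison for one outcome."""

    outcome: str
    f: float
    df: tuple[int, int]
    p: float
    eta_p_sq: float
    direction: int  # sign of the adjusted (group1 - group0) difference
    n_used: int

    def __str__(self) -> str:
        return (f"{self.outcome}: F({self.df[0]}, {self.df[1]}) = {self.f:.2f}, "
                f"p = {self.p:.4g}, eta_p^2 = {self.eta_p_sq:.3f}")


@dataclass
class RegressionResult:
    """Standardized multiple regression of one outcome."""

    outcome: str
    beta: dict[str, float]
    beta_p: dict[str, float]
    r_sq: float
    f: float
    df: tuple[int, int]
    p: float
    n_used: int

    def __str__(self) -> str:
        terms = ", ".join(f"{k}: beta={v:.2f}" for k, v in self.beta.items())
        return (f"{self.outcome} ~ [{terms}]; R^2 = {self.r_sq:.2f}, "
                f"F({self.df[0]}, {self.df[1]}) = {self.f:.2f}, p = {self.p:.4g}")


def log_transform(x):
    """ln(x + 1e-24); the offset keeps exact zeros finite.

    Negative input is rejected — the transform targets nonnegative
    connectivity/tree metrics.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("log transform defined for nonnegative values only")
    return np.log(x + LOG_OFFSET)


def bonferroni(pvals, m: int | None = None):
    """Bonferroni-adjusted p-values: min(1, p * m), order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"family size {m} smaller than {p.size} tests")
    return np.minimum(1.0, p * m)


def ancova_group_effect(
    table: pd.DataFrame,
    outcome: str,
    group_col: str = "group",
    covariates: tuple[str, ...] = ("age", "education", "premorbid_iq"),
) -> GroupEffect:
    """ANCOVA group effect on ``outcome`` with controlled covariates.

    Rows with a missing outcome, group or covariate are dropped listwise
    for this model only. df = (1, n - p - 1) with p = 1 + len(covariates).
    """
    cols = [outcome, group_col, *covariates]
    data = table[cols].dropna()
    groups = sorted(data[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    if min((data[group_col] == g).sum() for g in groups) < 2:
        raise ValueError("need >= 2 subjects per group")
    y = data[outcome].to_numpy(dtype=float)
    indicator = (data[group_col] == groups[1]).to_numpy(dtype=float)
    X_cov = data[list(covariates)].to_numpy(dtype=float) if covariates else \
        np.empty((len(data), 0))
    X_full = sm.add_constant(np.column_stack([indicator, X_cov]),
                             has_constant="add")
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("design matrix is rank-deficient (collinear "
                         "covariates or constant outcome predictor)")
    full = sm.OLS(y, X_full).fit()
    reduced = sm.OLS(y, sm.add_constant(X_cov, has_constant="add")).fit()
    ss_group = reduced.ssr - full.ssr
    ss_error = full.ssr
    df2 = int(full.df_resid)
    f = (ss_group / 1.0) / (ss_error / df2) if ss_error > 0 else np.inf
    f = max(f, 0.0)
    p = float(sps.f.sf(f, 1, df2))
    eta = ss_group / (ss_group + ss_error) if (ss_group + ss_error) > 0 else 0.0
    return GroupEffect(
        outcome=outcome, f=float(f), df=(1, df2), p=p,
        eta_p_sq=float(min(max(eta, 0.0), 1.0)),
        direction=int(np.sign(full.params[1])),
        n_used=len(data),
    )


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson r or Spearman R (midrank ties) with two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError("need n >= 4 for a correlation test")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def multiple_regression(
    table: pd.DataFrame,
    outcome: str,
    predictors: tuple[str, ...],
    controlled: tuple[str, ...] = ("duration_of_illness", "dup",
                                   "risperidone_equivalent"),
) -> RegressionResult:
    """OLS of the z-scored outcome on z-scored predictors + controls.

    Coefficients are therefore standardized betas. The overall test is
    F(k, n - k - 1) over all k regressors (predictors of interest and
    controlled predictors alike). Rank deficiency fails loudly, naming
    the collinear columns.
    """
    terms = [*predictors, *controlled]
    data = table[[outcome, *terms]].dropna()
    n = len(data)
    if n <= len(terms) + 1:
        raise ValueError(f"n = {n} too small for {len(terms)} predictors")

    def z(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError("zero-variance column in regression")
        return (v - v.mean()) / sd

    y = z(data[outcome].to_numpy(dtype=float))
    X = np.column_stack([z(data[t].to_numpy(dtype=float)) for t in terms])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [(terms[i], terms[j])
                 for i in range(len(terms)) for j in range(i + 1, len(terms))
                 if abs(corr[i, j]) > 1 - 1e-10]
        raise ValueError(f"rank-deficient design; collinear columns: {pairs}")
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    k = len(terms)
    return RegressionResult(
        outcome=outcome,
        beta={t: float(b) for t, b in zip(terms, fit.params[1:])},
        beta_p={t: float(p) for t, p in zip(terms, fit.pvalues[1:])},
        r_sq=float(fit.rsquared),
        f=float(fit.fvalue),
        df=(k, n - k - 1),
        p=float(fit.f_pvalue),
        n_used=n,
    )


def ks_normality(x) -> tuple[float, float]:
    """One-sample KS test of ``x`` against Normal(sample mean, sample SD).

    The reference distribution is fitted from the same sample, so the
    returned p is anti-conservative (the Lilliefors caveat); here the
    test is used only as the screen for "does not deviate from normal".
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 5:
        raise ValueError("need n >= 5")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    d, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return float(d), float(p)
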