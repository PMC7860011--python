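"""Cohort-level statistics: methylation-extreme accounting, rank and
contingency tests, and Bayesian logistic regression for multivariate analysis.

The extreme-methylation report counts beta observations above a
hypermethylation threshold (> 0.8) and below a hypomethylation threshold
(< 0.1) per cohort and expresses the FP excess as a percent difference.
The Bayesian logistic regression is a penalized maximum-a-posteriori fit
with independent Cauchy priors on standardized coefficients, which keeps
estimates finite under the complete separation that small cohorts produce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import BetaMatrix, ValidationError


@dataclass
class ExtremesReport:
    """Per-cohort counts of extreme beta observations and their FP/SD contrast."""

    hi_threshold: float
    lo_threshold: float
    mode: str
    count_high: dict[str, int]
    count_low: dict[str, int]
    n_observations: dict[str, int]

    def percent_difference_high(self, a: str = "FP", b: str = "SD") -> float:
        """(count_a / count_b - 1) * 100 for the hypermethylated tail."""
        return (self.count_high[a] / self.count_high[b] - 1.0) * 100.0

    def percent_difference_low(self, a: str = "FP", b: str = "SD") -> float:
        return (self.count_low[a] / self.count_low[b] - 1.0) * 100.0


def percent_excess(count_a: int, count_b: int) -> float:
    """Percent by which ``count_a`` exceeds ``count_b``: (a/b - 1) * 100."""
    if count_b <= 0:
        raise ValidationError("reference count must be positive")
    return (count_a / count_b - 1.0) * 100.0


def count_methylation_extremes(
    beta: BetaMatrix,
    groups: pd.Series,
    hi: float = 0.8,
    lo: float = 0.1,
    mode: str = "per-observation",
) -> ExtremesReport:
    """Count beta values > ``hi`` and < ``lo`` per cohort.

    ``mode="per-observation"`` pools all sample x probe cells (the default,
    matching histogram-style accounting over all beta-values);
    ``mode="per-probe-mean"`` counts probes whose cohort-mean beta is extreme.
    """
    if hi <= lo:
        raise ValidationError("hi threshold must exceed lo threshold")
    if mode not in ("per-observation", "per-probe-mean"):
        raise ValidationError(f"unknown mode {mode!r}")
    groups = pd.Series(groups).loc[beta.df.index]
    count_high: dict[str, int] = {}
    count_low: dict[str, int] = {}
    n_obs: dict[str, int] = {}
    for lv in sorted(groups.unique()):
        sel = (groups == lv).to_numpy()
        if sel.sum() == 0:
            raise ValidationError(f"cohort {lv!r} is empty")
        vals = beta.values[sel]
        if mode == "per-probe-mean":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                vals = np.nanmean(vals, axis=0)
        ok = ~np.isnan(vals)
        count_high[lv] = int((vals[ok] > hi).sum())
        count_low[lv] = int((vals[ok] < lo).sum())
        n_obs[lv] = int(ok.sum())
    return ExtremesReport(
        hi_threshold=hi,
        lo_threshold=lo,
        mode=mode,
        count_high=count_high,
        count_low=count_low,
        n_observations=n_obs,
    )


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p when min(n) <= 8 and there are no ties, otherwise the normal
    approximation with tie correction and continuity correction. Returns
    (U of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table, without continuity correction.

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), df = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValidationError("table entries must be nonnegative integers")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValidationError("chi-square undefined: a table margin is zero")
    chi2 = n * (a * d - b * c) ** 2 / np.prod(margins)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


@dataclass
class BayesLogitFit:
    """MAP logistic fit: per-covariate coefficient, SE, Wald z and p."""

    table: pd.DataFrame  # index: covariate; columns: coef, se, z, p
    prior_scale: float
    converged: bool

    def significant(self, alpha: float = 0.05) -> list[str]:
        t = self.table.drop(index="(intercept)", errors="ignore")
        return list(t.index[t["p"] < alpha])


def bayes_logistic(
    design: pd.DataFrame,
    outcome: pd.Series,
    prior_scale: float = 2.5,
    intercept_scale: float = 10.0,
    max_iter: int = 500,
) -> BayesLogitFit:
    """Penalized MAP logistic regression with independent Cauchy priors.

    Covariates are standardized internally (continuous: mean 0 / sd 1;
    binary: shifted to mean 0) and receive Cauchy(0, ``prior_scale``) priors;
    the intercept prior scale is ``intercept_scale``. Coefficients are
    reported back on the original covariate scale. Wald z and two-sided p
    come from the observed-information standard errors at the MAP. The
    heavy-tailed prior guarantees finite estimates under complete separation.
    """
    if design.shape[1] < 1:
        raise ValidationError("need at least one covariate")
    y_raw = pd.Series(outcome).loc[design.index]
    levels = sorted(y_raw.unique())
    if len(levels) != 2:
        raise ValidationError(f"outcome needs exactly two classes, got {levels}")
    # FP (or the second level) is coded 1
    positive = "FP" if "FP" in levels else levels[1]
    y = (y_raw == positive).to_numpy(dtype=float)

    X_raw = design.to_numpy(dtype=float)
    centers = X_raw.mean(axis=0)
    scales = np.ones(X_raw.shape[1])
    for j in range(X_raw.shape[1]):
        col = X_raw[:, j]
        if np.unique(col).size > 2:
            sd = col.std(ddof=1)
            if sd > 0:
                scales[j] = sd
    Xs = (X_raw - centers) / scales
    X = np.column_stack([np.ones(len(y)), Xs])
    prior = np.concatenate([[intercept_scale], np.full(Xs.shape[1], prior_scale)])

    def neg_log_post(b: np.ndarray) -> float:
        eta = X @ b
        # log(1 + e^-|eta|) formulation is numerically stable
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        lp = -np.sum(np.log1p((b / prior) ** 2))
        return -(ll + lp)

    def grad(b: np.ndarray) -> np.ndarray:
        eta = X @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        g_ll = X.T @ (y - mu)
        g_lp = -2.0 * b / (prior**2 + b**2)
        return -(g_ll + g_lp)

    res = optimize.minimize(
        neg_log_post,
        np.zeros(X.shape[1]),
        jac=grad,
        method="BFGS",
        options={"maxiter": max_iter, "gtol": 1e-8},
    )
    if not res.success and np.linalg.norm(grad(res.x)) > 1e-3:
        raise ValidationError(
            f"bayes_logistic did not converge after {max_iter} iterations: {res.message}"
        )
    b = res.x
    eta = X @ b
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = X.T @ (X * w[:, None])
    curv = 2.0 * (prior**2 - b**2) / (prior**2 + b**2) ** 2
    H_post = H + np.diag(np.maximum(curv, 0.0))
    cov = np.linalg.pinv(H_post)
    se_std = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    # back-transform to the original covariate scale
    coef = np.empty_like(b)
    se = np.empty_like(se_std)
    coef[1:] = b[1:] / scales
    se[1:] = se_std[1:] / scales
    coef[0] = b[0] - np.sum(b[1:] * centers / scales)
    se[0] = se_std[0]
    z = np.divide(coef, se, out=np.zeros_like(coef), where=se > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {"coef": coef, "se": se, "z": z, "p": p},
        index=["(intercept)"] + list(design.columns),
    )
    return BayesLogitFit(table=table, prior_scale=prior_scale, converged=bool(res.success))
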