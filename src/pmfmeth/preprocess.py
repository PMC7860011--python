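"""Quality filtering, BMIQ normalization, batch correction and confounder screening.

Pipeline order (mirrors routine EPIC-array practice): detection-p filtering,
intra-sample BMIQ probe-type normalization, then — for the statistics branch
only — ComBat batch correction on M-values. Data fed to panel selection and
classification are deliberately NOT batch corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betainc

from .datatypes import (
    BetaMatrix,
    FilterReport,
    ValidationError,
    inv_logit_m,
    logit_clamped,
)


class EmptyCohortError(ValidationError):
    """All samples were excluded by quality filtering."""


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(f"{message} (last objective values: {trace[-5:]})")
        self.trace = trace


# ---------------------------------------------------------------------------
# detection-p filtering
# ---------------------------------------------------------------------------

def filter_by_detection(
    beta: BetaMatrix,
    detp: pd.DataFrame,
    p_thresh: float = 0.1,
    probe_fail_frac: float = 0.05,
    sample_fail_frac: float = 0.1,
) -> tuple[BetaMatrix, FilterReport]:
    """Exclude failing samples, then failing probes, by detection p-value.

    A sample is excluded when more than ``sample_fail_frac`` of its probes
    have detection p > ``p_thresh``; afterwards a probe is excluded when it
    fails in more than ``probe_fail_frac`` of the remaining samples.
    Surviving beta-values are returned unchanged. The operation is idempotent.
    """
    if not (0 < p_thresh < 1):
        raise ValidationError("p_thresh must lie in (0, 1)")
    dp = detp.loc[beta.df.index, beta.df.columns]
    failed = dp.to_numpy() > p_thresh

    sample_frac = failed.mean(axis=1)
    keep_samples = sample_frac <= sample_fail_frac
    excluded_samples = {
        str(s): float(f)
        for s, f in zip(beta.df.index[~keep_samples], sample_frac[~keep_samples])
    }
    if not keep_samples.any():
        raise EmptyCohortError("empty cohort: all samples exceeded the detection-p limit")

    probe_frac = failed[keep_samples].mean(axis=0)
    n_kept = int(keep_samples.sum())
    keep_probes = probe_frac <= probe_fail_frac
    excluded_probes = {
        str(p): f"detection p > {p_thresh:g} in {int(round(f * n_kept))}/{n_kept} samples"
        for p, f in zip(beta.df.columns[~keep_probes], probe_frac[~keep_probes])
    }
    out = BetaMatrix(beta.df.loc[keep_samples, keep_probes])
    report = FilterReport(
        excluded_samples=excluded_samples,
        excluded_probes=excluded_probes,
        n_evaluable=int(keep_probes.sum()),
    )
    return out, report


# ---------------------------------------------------------------------------
# BMIQ: beta-mixture quantile normalization of type II probes
# ---------------------------------------------------------------------------

def _weighted_beta_mle(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Beta(a, b) fit with observation weights."""
    sw = w.sum()
    if sw <= 0:
        return 1.0, 1.0
    m = float((w * x).sum() / sw)
    v = float((w * (x - m) ** 2).sum() / sw)
    m = min(max(m, 1e-4), 1 - 1e-4)
    v = max(min(v, m * (1 - m) * 0.999), 1e-6)
    common = m * (1 - m) / v - 1.0
    return max(m * common, 1e-2), max((1 - m) * common, 1e-2)


def fit_beta_mixture(
    x: np.ndarray,
    n_states: int = 3,
    tol: float = 1e-5,
    max_iter: int = 1000,
) -> dict:
    """EM fit of an ``n_states``-component beta mixture to values in (0, 1).

    Components are initialised from quantile-split groups and returned sorted
    by mean. Assignment ties are broken toward the lower-mean state.
    """
    x = np.clip(np.asarray(x, dtype=float), 1e-4, 1 - 1e-4)
    n = x.size
    # quantile initialisation of 3 states (k-means-style 1-D seeding)
    order = np.argsort(x)
    splits = np.array_split(order, n_states)
    weights = np.array([len(s) / n for s in splits])
    params = [_weighted_beta_mle(x[s], np.ones(len(s))) for s in splits]

    trace: list[float] = []
    ll_old = -np.inf
    for _ in range(max_iter):
        dens = np.stack(
            [w * stats.beta.pdf(x, a, b) for w, (a, b) in zip(weights, params)]
        )
        total = dens.sum(axis=0)
        total[total <= 0] = 1e-300
        ll = float(np.log(total).sum())
        trace.append(ll)
        resp = dens / total
        weights = resp.sum(axis=1) / n
        params = [_weighted_beta_mle(x, resp[k]) for k in range(n_states)]
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    else:
        raise ConvergenceError("beta-mixture EM did not converge", trace)

    means = np.array([a / (a + b) for a, b in params])
    order = np.argsort(means)
    weights = weights[order]
    params = [params[k] for k in order]
    dens = np.stack([w * stats.beta.pdf(x, a, b) for w, (a, b) in zip(weights, params)])
    # np.argmax takes the first maximum: ties break toward the lower-mean state
    assign = dens.argmax(axis=0)
    return {"weights": weights, "params": params, "assign": assign, "loglik": trace[-1]}


def bmiq_normalize(
    beta_row: np.ndarray | pd.Series,
    design_type: np.ndarray | pd.Series,
    min_per_type: int = 100,
    tol: float = 1e-5,
    max_iter: int = 1000,
) -> np.ndarray:
    """Intra-sample BMIQ: map type II probes onto the type I state distributions.

    A 3-state beta mixture (unmethylated / hemimethylated / methylated) is fit
    separately to the type I and type II probes of one sample. Type II probes
    in the outer states are quantile-mapped onto the corresponding type I
    state beta distribution; the middle state is rescaled linearly between the
    mapped outer states. Type I probes are returned unchanged; the transform
    is monotone non-decreasing over the type II probes and stays in [0, 1].
    """
    x = np.asarray(pd.Series(beta_row), dtype=float)
    dt = np.asarray(pd.Series(design_type), dtype=object)
    out = x.copy()
    t1 = (dt == "I") & ~np.isnan(x)
    t2 = (dt == "II") & ~np.isnan(x)
    if t1.sum() < min_per_type or t2.sum() < min_per_type:
        raise ValidationError(
            f"BMIQ needs >= {min_per_type} probes per design type "
            f"(got {int(t1.sum())} type I, {int(t2.sum())} type II)"
        )
    fit1 = fit_beta_mixture(x[t1], tol=tol, max_iter=max_iter)
    fit2 = fit_beta_mixture(x[t2], tol=tol, max_iter=max_iter)

    x2 = np.clip(x[t2], 1e-4, 1 - 1e-4)
    assign2 = fit2["assign"]
    mapped = x2.copy()

    a_u1, b_u1 = fit1["params"][0]
    a_u2, b_u2 = fit2["params"][0]
    a_m1, b_m1 = fit1["params"][2]
    a_m2, b_m2 = fit2["params"][2]

    u_mask = assign2 == 0
    m_mask = assign2 == 2
    h_mask = assign2 == 1
    if u_mask.any():
        p = betainc(a_u2, b_u2, x2[u_mask])
        mapped[u_mask] = stats.beta.ppf(np.clip(p, 1e-12, 1 - 1e-12), a_u1, b_u1)
    if m_mask.any():
        p = betainc(a_m2, b_m2, x2[m_mask])
        mapped[m_mask] = stats.beta.ppf(np.clip(p, 1e-12, 1 - 1e-12), a_m1, b_m1)
    if h_mask.any():
        # linear dilation of the middle state between the mapped outer states
        lo = x2[u_mask].max() if u_mask.any() else x2[h_mask].min()
        hi = x2[m_mask].min() if m_mask.any() else x2[h_mask].max()
        n_lo = mapped[u_mask].max() if u_mask.any() else lo
        n_hi = mapped[m_mask].min() if m_mask.any() else hi
        span = hi - lo
        if span <= 0:
            span = 1.0
        mapped[h_mask] = n_lo + (x2[h_mask] - lo) / span * (n_hi - n_lo)

    # enforce global monotonicity over the type II probes (state-boundary
    # artefacts of the three separate maps are ironed out here)
    order = np.argsort(x2, kind="stable")
    mapped[order] = np.maximum.accumulate(mapped[order])
    out[t2] = np.clip(mapped, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# ComBat batch correction (parametric empirical Bayes, on M-values)
# ---------------------------------------------------------------------------

def _aprior(g: np.ndarray) -> float:
    m, v = g.mean(), g.var(ddof=1)
    return (2 * v + m ** 2) / v if v > 0 else 2.0


def _bprior(g: np.ndarray) -> float:
    m, v = g.mean(), g.var(ddof=1)
    return (m * v + m ** 3) / v if v > 0 else 1.0


def _it_sol(
    sdat: np.ndarray,
    g_hat: np.ndarray,
    d_hat: np.ndarray,
    g_bar: float,
    t2: float,
    a: float,
    b: float,
    conv: float = 1e-4,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative solution for the parametric EB batch estimates (per probe)."""
    n = (~np.isnan(sdat)).sum(axis=1)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    trace: list[float] = []
    for _ in range(max_iter):
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = np.nansum((sdat - g_new[:, None]) ** 2, axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).clip(1e-12).max(),
            np.abs(d_new - d_old).max() / np.abs(d_old).clip(1e-12).max(),
        )
        trace.append(float(change))
        g_old, d_old = g_new, d_new
        if change < conv:
            return g_new, d_new
    raise ConvergenceError("ComBat EB iteration did not converge", trace)


def combat_correct(
    beta: BetaMatrix,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> BetaMatrix:
    """Remove per-probe location/scale batch effects with parametric ComBat.

    Beta-values are mapped to M-values (clamped logit), batch effects are
    estimated by the empirical-Bayes shrinkage scheme (normal prior on
    locations, inverse-gamma on scales) while protecting the ``covariates``
    (e.g. the FP/SD group) design, and the corrected M-values are mapped back.
    """
    batch = pd.Series(batch).loc[beta.df.index]
    levels = batch.unique()
    counts = batch.value_counts()
    if (counts < 2).any():
        raise ValidationError(f"every batch needs >= 2 samples; sizes: {counts.to_dict()}")
    if len(levels) == 1:
        return BetaMatrix(beta.df.copy())

    m = logit_clamped(beta.values).T  # probes x samples
    n_probes, n_samples = m.shape

    batch_design = pd.get_dummies(batch, dtype=float).loc[:, levels].to_numpy()
    design_parts = [batch_design]
    if covariates is not None:
        cov = pd.get_dummies(covariates.loc[beta.df.index], drop_first=True, dtype=float)
        design_parts.append(cov.to_numpy(dtype=float))
    design = np.column_stack(design_parts)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError(
            "batch is confounded with the protected covariates; effects inestimable"
        )

    n_batch = len(levels)
    beta_hat = np.linalg.lstsq(design, m.T, rcond=None)[0]  # coefs x probes
    batch_sizes = np.array([counts[lv] for lv in levels], dtype=float)
    grand_mean = (batch_sizes / n_samples) @ beta_hat[:n_batch]
    stand_mean = grand_mean[:, None] * np.ones((1, n_samples))
    if design.shape[1] > n_batch:
        stand_mean = stand_mean + (design[:, n_batch:] @ beta_hat[n_batch:]).T
    resid = m - (design @ beta_hat).T
    var_pooled = (resid ** 2).mean(axis=1)
    var_pooled[var_pooled <= 0] = 1e-12

    s_data = (m - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_star = np.zeros((n_batch, n_probes))
    delta_star = np.ones((n_batch, n_probes))
    for i, lv in enumerate(levels):
        sel = (batch == lv).to_numpy()
        sdat = s_data[:, sel]
        g_hat = sdat.mean(axis=1)
        d_hat = sdat.var(axis=1, ddof=1)
        d_hat[d_hat <= 0] = 1e-12
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        a, b = _aprior(d_hat), _bprior(d_hat)
        gamma_star[i], delta_star[i] = _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b)

    adjusted = s_data.copy()
    for i, lv in enumerate(levels):
        sel = (batch == lv).to_numpy()
        adjusted[:, sel] = (adjusted[:, sel] - gamma_star[i][:, None]) / np.sqrt(
            delta_star[i]
        )[:, None]
    m_corr = adjusted * np.sqrt(var_pooled)[:, None] + stand_mean
    out = inv_logit_m(m_corr.T)
    return BetaMatrix(pd.DataFrame(out, index=beta.df.index, columns=beta.df.columns))


# ---------------------------------------------------------------------------
# SVD confounder screen
# ---------------------------------------------------------------------------

def svd_confounder_screen(
    beta: BetaMatrix,
    covariates: pd.DataFrame,
    n_components: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Associate top singular components of the beta matrix with sample variables.

    Each of the top ``min(20, n_samples - 1)`` left singular vectors of the
    probe-centred beta matrix is tested against every covariate
    (Kruskal-Wallis for categorical variables, Spearman rank correlation for
    numeric ones). Raw p-values and per-variable BH-adjusted q-values are
    returned; a variable is flagged as a potential confounder when any of its
    q-values falls below ``alpha``.
    """
    X = beta.values.copy()
    if X.shape[0] < 3:
        raise ValidationError("SVD screen needs at least 3 samples")
    col_mean = np.nanmean(X, axis=0)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = col_mean[nan_idx[1]]
    X = X - X.mean(axis=0)
    if n_components is None:
        n_components = min(20, X.shape[0] - 1)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    keep = s > s.max() * 1e-10
    comps = u[:, keep][:, :n_components]

    rows = []
    for var in covariates.columns:
        v = covariates[var].loc[beta.df.index]
        numeric = pd.api.types.is_numeric_dtype(v) and v.nunique() > 6
        if v.nunique() < 2:
            warnings.warn(f"covariate {var!r} is constant; skipped", stacklevel=2)
            continue
        pvals = []
        for k in range(comps.shape[1]):
            c = comps[:, k]
            if numeric:
                ok = ~pd.isna(v)
                _, p = stats.spearmanr(v[ok.to_numpy()], c[ok.to_numpy()])
            else:
                grps = [c[(v == lv).to_numpy()] for lv in v.dropna().unique()]
                grps = [g for g in grps if len(g) > 0]
                _, p = stats.kruskal(*grps)
            pvals.append(float(p))
        from .differential import benjamini_hochberg

        qvals = benjamini_hochberg(np.array(pvals))
        for k, (p, q) in enumerate(zip(pvals, qvals)):
            rows.append(
                {
                    "component": k + 1,
                    "variable": var,
                    "p": p,
                    "q": float(q),
                    "flagged": bool(q < alpha),
                }
            )
    return pd.DataFrame(rows)


def flagged_confounders(screen: pd.DataFrame) -> list[str]:
    """Variables flagged in any component of an ``svd_confounder_screen`` table."""
    if screen.empty:
        return []
    return sorted(screen.loc[screen["flagged"], "variable"].unique())
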