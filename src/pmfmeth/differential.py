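"""Probe-level (DMP) and region-level (DMR) differential methylation,
GO-style gene-set enrichment with probe-number bias correction, and the
hierarchical clustering used for heatmap ordering.

Testing is done on M-values (variance-stabilised logit scale); effect sizes
are reported as delta-beta on the interpretable beta scale. "Differentially
methylated" is a purely statistical definition: BH-FDR q <= 0.1, with no
additional delta-beta cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.special import digamma, polygamma

from .datatypes import BetaMatrix, ProbeAnnotation, ValidationError, logit_clamped


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR
# ---------------------------------------------------------------------------

def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH q-values with enforced monotonicity; order preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


# ---------------------------------------------------------------------------
# moderated-t DMP fit
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (Smyth-style)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x - dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment estimates of the prior df and scale of the variance prior.

    Matches the log-variance moments of a scaled F distribution: returns
    (d0, s0^2) with d0 possibly inf when the observed spread of log s^2 is no
    larger than expected from chi-square sampling alone.
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - polygamma(1, df / 2.0)
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def fit_dmp(
    beta: BetaMatrix,
    groups: pd.Series,
    prior_df: float | None = None,
    max_prior_df: float = 100.0,
    var_floor: float = 1e-12,
) -> pd.DataFrame:
    """Per-probe moderated-t group contrast on M-values.

    Ordinary least-squares two-group contrasts are computed per probe on the
    clamped-logit M scale; residual variances are shrunk toward a common
    prior estimated by moments matching on the log variances (empirical
    Bayes), and the moderated t uses df = residual df + prior df. q-values
    are BH; a probe counts as differentially methylated at q <= 0.1.

    ``prior_df`` overrides the estimated prior df (0 disables shrinkage and
    recovers the ordinary two-sample t).

    Returns a DataFrame sorted by ascending p (ties by descending |t|, then
    probe id) with columns probe_id, mean_fp, mean_sd, delta_beta,
    moderated_t, p, q, var_floored.
    """
    groups = pd.Series(groups).loc[beta.df.index]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValidationError(f"need exactly two groups, got {labels}")
    g_fp = "FP" if "FP" in labels else labels[0]
    g_sd = [l for l in labels if l != g_fp][0]
    sel_fp = (groups == g_fp).to_numpy()
    sel_sd = (groups == g_sd).to_numpy()
    if sel_fp.sum() < 2 or sel_sd.sum() < 2:
        raise ValidationError("need at least 2 samples per group")

    b = beta.values
    m = logit_clamped(b)
    m[np.isnan(b)] = np.nan

    def _group_stats(sel):
        vals = m[sel]
        n = (~np.isnan(vals)).sum(axis=0).astype(float)
        mean = np.nanmean(vals, axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ss = np.nansum((vals - mean) ** 2, axis=0)
        return n, mean, ss

    n1, mu1, ss1 = _group_stats(sel_fp)
    n2, mu2, ss2 = _group_stats(sel_sd)
    usable = (n1 >= 2) & (n2 >= 2)
    df_resid = n1 + n2 - 2.0
    s2 = np.where(usable, (ss1 + ss2) / np.where(df_resid > 0, df_resid, 1.0), np.nan)
    floored = usable & (s2 <= var_floor)
    s2 = np.where(floored, var_floor, s2)

    df_common = float(np.median(df_resid[usable]))
    if prior_df is None:
        d0, s0_sq = _fit_f_dist(s2[usable], df_common)
        d0 = min(d0, max_prior_df)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 1.0
    else:
        d0 = float(prior_df)
        _, s0_sq = _fit_f_dist(s2[usable], df_common)
    if np.isfinite(d0) and d0 > 0:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
    elif d0 == 0:
        s2_post = s2
    else:  # infinite prior df: fully pooled variance
        d0 = max_prior_df
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    tstat = (mu1 - mu2) / se
    df_total = df_resid + d0
    p = 2.0 * stats.t.sf(np.abs(tstat), df_total)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_fp = np.nanmean(b[sel_fp], axis=0)
        mean_sd = np.nanmean(b[sel_sd], axis=0)

    out = pd.DataFrame(
        {
            "probe_id": beta.df.columns,
            "mean_fp": mean_fp,
            "mean_sd": mean_sd,
            "delta_beta": mean_fp - mean_sd,
            "moderated_t": tstat,
            "p": p,
            "var_floored": floored,
        }
    )
    out = out[usable].reset_index(drop=True)
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    out = out.sort_values(
        ["p", "moderated_t", "probe_id"],
        ascending=[True, False, True],
        key=lambda c: c.abs() if c.name == "moderated_t" else c,
        kind="stable",
    ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# bump-hunting DMRs
# ---------------------------------------------------------------------------

@dataclass
class DMRRecord:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    probe_ids: list[str]
    area: float
    p: float
    q: float


def _clusters(chrom: np.ndarray, pos: np.ndarray, max_gap: int) -> list[np.ndarray]:
    """Indices grouped so that consecutive within-cluster gaps are <= max_gap."""
    order = np.lexsort((pos, chrom))
    groups: list[np.ndarray] = []
    current: list[int] = []
    for idx in order:
        if current and (
            chrom[idx] != chrom[current[-1]] or pos[idx] - pos[current[-1]] > max_gap
        ):
            groups.append(np.array(current))
            current = []
        current.append(idx)
    if current:
        groups.append(np.array(current))
    return groups


def _candidate_bumps(
    coef: np.ndarray, clusters: list[np.ndarray], cutoff: float
) -> list[np.ndarray]:
    """Maximal same-sign runs of probes whose |coefficient| exceeds the cutoff."""
    bumps = []
    for cl in clusters:
        run: list[int] = []
        run_sign = 0
        for idx in cl:
            c = coef[idx]
            sign = 0 if (np.isnan(c) or abs(c) < cutoff) else (1 if c > 0 else -1)
            if sign != 0 and (sign == run_sign or not run):
                run.append(idx)
                run_sign = sign
            else:
                if run:
                    bumps.append(np.array(run))
                run = [idx] if sign != 0 else []
                run_sign = sign
        if run:
            bumps.append(np.array(run))
    return bumps


def find_dmrs(
    beta: BetaMatrix,
    groups: pd.Series,
    annotation: ProbeAnnotation,
    max_gap: int = 250,
    cutoff_quantile: float = 0.99,
    n_perm: int = 250,
    fdr: float = 0.05,
    seed: int = 0,
) -> list[DMRRecord]:
    """Bump-hunting DMR detection with a permutation null.

    Probes are clustered so consecutive gaps are <= ``max_gap``; candidate
    bumps are maximal same-sign runs where the per-probe beta-scale group
    coefficient exceeds the ``cutoff_quantile`` of all |coefficients|; the
    bump statistic is the area (sum of |coefficients|). The null distribution
    comes from group-label permutations: p is the fraction of permutations
    whose maximal bump area reaches the observed one (family-wise style,
    conservative). Bumps with BH q <= ``fdr`` are returned.
    """
    if n_perm < 10:
        raise ValidationError("n_perm < 10 gives an unstable permutation null")
    groups = pd.Series(groups).loc[beta.df.index]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValidationError(f"need exactly two groups, got {labels}")
    ann = annotation.for_probes(beta.probe_ids)
    chrom = ann["chr"].to_numpy()
    pos = ann["pos"].to_numpy()
    b = beta.values
    sel = (groups == labels[0]).to_numpy()

    def _coefs(mask: np.ndarray) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(b[mask], axis=0) - np.nanmean(b[~mask], axis=0)

    coef = _coefs(sel)
    cutoff = float(np.nanquantile(np.abs(coef), cutoff_quantile))
    clusters = _clusters(chrom, pos, max_gap)
    bumps = _candidate_bumps(coef, clusters, cutoff)
    if not bumps:
        return []
    areas = np.array([np.abs(coef[bp]).sum() for bp in bumps])

    rng = np.random.default_rng(seed)
    n_samples = b.shape[0]
    n_g1 = int(sel.sum())
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        perm = np.zeros(n_samples, dtype=bool)
        perm[rng.choice(n_samples, n_g1, replace=False)] = True
        pc = _coefs(perm)
        pb = _candidate_bumps(pc, clusters, cutoff)
        if pb:
            null_max[i] = max(np.abs(pc[bp]).sum() for bp in pb)

    p = np.array([(1.0 + (null_max >= a).sum()) / (n_perm + 1.0) for a in areas])
    q = benjamini_hochberg(p)

    records = []
    probe_ids = np.asarray(beta.probe_ids)
    for bp, a, pv, qv in zip(bumps, areas, p, q):
        if qv <= fdr:
            records.append(
                DMRRecord(
                    chrom=str(chrom[bp[0]]),
                    start=int(pos[bp].min()),
                    end=int(pos[bp].max()),
                    probe_ids=[str(x) for x in probe_ids[bp]],
                    area=float(a),
                    p=float(pv),
                    q=float(qv),
                )
            )
    records.sort(key=lambda r: (r.p, r.chrom, r.start))
    return records


# ---------------------------------------------------------------------------
# gene-set enrichment with probe-number bias (Wallenius)
# ---------------------------------------------------------------------------

def gene_set_enrichment(
    hit_genes: set[str],
    annotation: ProbeAnnotation,
    gene_sets: dict[str, list[str]],
) -> pd.DataFrame:
    """Per-term enrichment of ``hit_genes`` with probe-count selection bias.

    Genes with many probes on the array are more likely to contain a
    significant CpG by chance; the per-term p-value therefore uses a
    Wallenius noncentral hypergeometric approximation with gene weight
    proportional to its probe count (the odds is the ratio of the mean probe
    count inside vs outside the term). Terms are significant at BH q <= 0.1.
    """
    if not gene_sets:
        raise ValidationError("gene_sets must be nonempty")
    genes = annotation.df["gene"]
    counts = genes[genes != ""].value_counts()
    universe = set(counts.index)
    dropped = set(hit_genes) - universe
    if dropped:
        warnings.warn(
            f"{len(dropped)} hit gene(s) absent from the array universe; dropped",
            stacklevel=2,
        )
    hits = set(hit_genes) & universe
    n_universe = len(universe)
    n_hits = len(hits)

    rows = []
    for term_id, members in gene_sets.items():
        in_term = set(members) & universe
        n_term = len(in_term)
        if n_term == 0:
            continue
        k = len(in_term & hits)
        mean_in = counts[list(in_term)].mean()
        out_genes = universe - in_term
        mean_out = counts[list(out_genes)].mean() if out_genes else mean_in
        odds = float(mean_in / mean_out) if mean_out > 0 else 1.0
        if n_hits == 0:
            p = 1.0
        elif abs(odds - 1.0) < 1e-9:
            p = float(stats.hypergeom.sf(k - 1, n_universe, n_term, n_hits))
        else:
            dist = stats.nchypergeom_wallenius(n_universe, n_term, n_hits, odds)
            p = float(dist.sf(k - 1))
        rows.append(
            {
                "term_id": term_id,
                "n_genes_in_term": n_term,
                "n_hit": k,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# clustering / heatmap ordering
# ---------------------------------------------------------------------------

def cluster_heatmap_order(
    beta: BetaMatrix,
    records: pd.DataFrame,
    top_n: int,
) -> tuple[list[str], list[str], dict]:
    """Centroid-linkage clustering of the ``top_n`` most significant probes.

    Probes are ranked by ascending p (the DMP table's order); samples and
    probes are clustered separately by centroid linkage on Euclidean
    beta-value distance. Returns (probe leaf order, sample leaf order,
    {"probe_linkage": Z_p, "sample_linkage": Z_s}).
    """
    if top_n < 2:
        raise ValidationError("top_n must be >= 2")
    if top_n > len(records):
        raise ValidationError(f"top_n={top_n} exceeds the {len(records)} available records")
    probes = records["probe_id"].head(top_n).tolist()
    sub = beta.select_probes(probes)
    X = sub.values
    col_mean = np.nanmean(X, axis=0)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = col_mean[nan_idx[1]]
    z_samples = hierarchy.linkage(X, method="centroid", metric="euclidean")
    z_probes = hierarchy.linkage(X.T, method="centroid", metric="euclidean")
    sample_order = [sub.sample_ids[i] for i in hierarchy.leaves_list(z_samples)]
    probe_order = [probes[i] for i in hierarchy.leaves_list(z_probes)]
    return probe_order, sample_order, {"probe_linkage": z_probes, "sample_linkage": z_samples}
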