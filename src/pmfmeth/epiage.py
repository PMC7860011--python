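"""Epigenetic-clock scoring and epigenetic-vs-chronological age statistics.

A clock is a linear model age = intercept + sum_i w_i * beta_i (PhenoAge-style).
Clock coefficients are data, not code: they are read from a two-column CSV
(probe_id, weight) whose ``intercept`` row carries the offset, so any published
coefficient set can be dropped in. The analyses compare the resulting
epigenetic age (EA) with the known chronological age (CA): a per-group count
of EA > CA cases (chi-square test) and a group comparison of EA - CA
(Mann-Whitney U).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohortstats import chi_square_2x2, mann_whitney_u
from .datatypes import BetaMatrix, ClockModel, ValidationError


def read_clock(path: str | Path, name: str | None = None) -> ClockModel:
    """Read a clock CSV (probe_id, weight); the ``intercept`` row is the offset."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"probe_id", "weight"}.issubset(df.columns):
        raise ValidationError("clock CSV needs columns probe_id, weight")
    is_intercept = df["probe_id"].str.strip().str.lower().isin({"intercept", "(intercept)"})
    if is_intercept.sum() != 1:
        raise ValidationError("clock CSV needs exactly one intercept row")
    intercept = float(df.loc[is_intercept, "weight"].iloc[0])
    weights = dict(
        zip(df.loc[~is_intercept, "probe_id"], df.loc[~is_intercept, "weight"].astype(float))
    )
    return ClockModel(intercept=intercept, weights=weights, name=name or Path(path).stem)


def compute_epigenetic_age(
    beta: BetaMatrix,
    clock: ClockModel,
    ages: pd.Series | None = None,
    missing_policy: str = "mean",
    min_coverage: float = 0.8,
) -> pd.DataFrame:
    """Score every sample with the clock: ea = intercept + sum w_i * beta_i.

    Clock probes missing in a sample (absent column or masked value) are
    imputed with the cohort mean beta under ``missing_policy="mean"`` or raise
    under ``"strict"``. Samples covering less than ``min_coverage`` of the
    clock probes raise, naming the missing probes.

    Returns a DataFrame indexed by sample id with columns ea, ca, delta
    (ca/delta are NaN when ``ages`` is not given).
    """
    if missing_policy not in ("mean", "strict"):
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    probes = clock.probe_ids
    present = [p for p in probes if p in beta.df.columns]
    absent = [p for p in probes if p not in beta.df.columns]
    sub = beta.df.loc[:, present].to_numpy(dtype=float)
    w = np.array([clock.weights[p] for p in present])
    n_clock = len(probes)

    missing_mask = np.isnan(sub)
    coverage = (n_clock - len(absent) - missing_mask.sum(axis=1)) / n_clock
    low = coverage < min_coverage
    if low.any():
        sid = beta.df.index[low][0]
        i = int(np.where(low)[0][0])
        miss = list(absent) + [present[j] for j in np.where(missing_mask[i])[0]]
        raise ValidationError(
            f"sample {sid!r} covers {coverage[low][0]:.0%} of clock probes "
            f"(< {min_coverage:.0%}); missing: {miss[:10]}"
        )
    if absent and missing_policy == "strict":
        raise ValidationError(f"clock probes absent from matrix: {absent[:10]}")
    if missing_mask.any():
        if missing_policy == "strict":
            raise ValidationError("masked clock beta-values under strict policy")
        col_mean = np.nanmean(sub, axis=0)
        idx = np.where(missing_mask)
        sub[idx] = col_mean[idx[1]]

    ea = clock.intercept + sub @ w
    out = pd.DataFrame({"ea": ea}, index=beta.df.index)
    if ages is not None:
        out["ca"] = pd.Series(ages).loc[beta.df.index].astype(float)
    else:
        out["ca"] = np.nan
    out["delta"] = out["ea"] - out["ca"]
    out.index.name = "sample_id"
    return out


def ea_ca_contingency(
    results: pd.DataFrame, groups: pd.Series
) -> tuple[pd.DataFrame, float, float]:
    """2x2 table of EA > CA (strict) vs not, by group, with Pearson chi-square.

    delta == 0 counts as "not larger". Returns (table, chi2, p); the table has
    groups as rows and columns ``ea_gt_ca`` / ``ea_le_ca``.
    """
    groups = pd.Series(groups).loc[results.index]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValidationError(f"need exactly two groups, got {labels}")
    labels = ["FP", "SD"] if set(labels) == {"FP", "SD"} else labels
    table = []
    for lv in labels:
        sel = (groups == lv).to_numpy()
        if sel.sum() == 0:
            raise ValidationError(f"group {lv!r} has no samples")
        gt = int((results.loc[sel, "delta"] > 0).sum())
        table.append([gt, int(sel.sum()) - gt])
    tab = pd.DataFrame(table, index=labels, columns=["ea_gt_ca", "ea_le_ca"])
    chi2, p = chi_square_2x2(tab.to_numpy())
    return tab, chi2, p


def group_age_difference(results: pd.DataFrame, groups: pd.Series) -> dict:
    """Per-group mean EA, CA and EA-CA, plus a two-sided Mann-Whitney p on delta."""
    groups = pd.Series(groups).loc[results.index]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValidationError(f"need exactly two groups, got {labels}")
    labels = ["FP", "SD"] if set(labels) == {"FP", "SD"} else labels
    summary = {}
    deltas = []
    for lv in labels:
        sel = (groups == lv).to_numpy()
        if sel.sum() < 2:
            raise ValidationError(f"group {lv!r} needs >= 2 samples")
        r = results.loc[sel]
        summary[lv] = {
            "mean_ea": float(r["ea"].mean()),
            "mean_ca": float(r["ca"].mean()),
            "mean_delta": float(r["delta"].mean()),
            "n": int(sel.sum()),
        }
        deltas.append(r["delta"].to_numpy())
    _, p = mann_whitney_u(deltas[0], deltas[1])
    summary["p_mann_whitney"] = float(p)
    return summary
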