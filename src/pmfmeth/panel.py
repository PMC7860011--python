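"""Minimal CpG-panel selection and linear discriminant classification.

Feature subsets are scored by the tau-squared separation criterion
(tau^2 = 1 - Wilks' Lambda for two groups, Lambda = det(E)/det(T) with E the
within-group and T the total scatter matrix). The exact best subset of each
size is found by branch and bound, using the monotone bound
tau^2(S) <= tau^2(S') for S subset of S' as the pruning rule, so the search
is equivalent to exhaustive enumeration. The selected panel feeds a two-class
linear discriminant model whose one-dimensional projection (LD1) carries the
decision threshold and the class-probability confidence bands.

Panel selection is intentionally run on non-batch-corrected beta-values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .datatypes import ValidationError

_RIDGE = 1e-6


@dataclass
class SubsetScore:
    probe_ids: tuple[str, ...]
    tau_squared: float
    wilks_lambda: float


@dataclass
class PanelModel:
    """Fitted LDA panel: probe ids, LD1 weights, projected centroids, threshold.

    The weights are normalised so the projected pooled within-group variance
    is 1, with the sign fixed so the FP centroid projects negative.
    """

    probe_ids: list[str]
    weights: np.ndarray
    center: np.ndarray  # feature-space centering point (mean of class centroids)
    mean_fp: float  # projected FP centroid
    mean_sd: float  # projected SD centroid
    priors: tuple[float, float]  # (FP, SD)
    threshold: float
    tau_squared: float | None = None
    non_separating: bool = False

    def to_json(self, path: str | Path) -> None:
        payload = {
            "probe_ids": list(self.probe_ids),
            "weights": [float(w) for w in self.weights],
            "center": [float(c) for c in self.center],
            "mean_fp": self.mean_fp,
            "mean_sd": self.mean_sd,
            "priors": list(self.priors),
            "threshold": self.threshold,
            "tau_squared": self.tau_squared,
            "non_separating": self.non_separating,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PanelModel":
        d = json.loads(Path(path).read_text())
        return cls(
            probe_ids=d["probe_ids"],
            weights=np.asarray(d["weights"], dtype=float),
            center=np.asarray(d["center"], dtype=float),
            mean_fp=d["mean_fp"],
            mean_sd=d["mean_sd"],
            priors=tuple(d["priors"]),
            threshold=d["threshold"],
            tau_squared=d.get("tau_squared"),
            non_separating=d.get("non_separating", False),
        )


def _group_masks(groups: pd.Series, index) -> tuple[np.ndarray, np.ndarray]:
    groups = pd.Series(groups).loc[index]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValidationError(f"need exactly two groups, got {labels}")
    g_fp = "FP" if "FP" in labels else labels[0]
    g_sd = [l for l in labels if l != g_fp][0]
    fp = (groups == g_fp).to_numpy()
    sd = (groups == g_sd).to_numpy()
    if fp.sum() < 2 or sd.sum() < 2:
        raise ValidationError("need at least 2 samples per group")
    return fp, sd


def _scatter_matrices(X: np.ndarray, fp: np.ndarray, sd: np.ndarray):
    """Within-group scatter E and total scatter T for a two-group design."""
    mu_fp = X[fp].mean(axis=0)
    mu_sd = X[sd].mean(axis=0)
    mu = X.mean(axis=0)
    r_fp = X[fp] - mu_fp
    r_sd = X[sd] - mu_sd
    E = r_fp.T @ r_fp + r_sd.T @ r_sd
    R = X - mu
    T = R.T @ R
    return E, T


def _lambda_from_scatter(E: np.ndarray, T: np.ndarray) -> float:
    """Wilks' Lambda = det(E)/det(T), computed stably.

    T is Cholesky-whitened and Lambda taken as the product of the eigenvalues
    of L^-1 E L^-T, which lie in [0, 1] because E <= T in the PSD order; the
    clipping keeps the quantity well defined under severe rank deficiency
    (where the raw determinant ratio is numerically meaningless).
    """
    from scipy.linalg import solve_triangular

    k = E.shape[0]
    tr = np.trace(T)
    ridge = _RIDGE * (tr / k if tr > 0 else 1.0)
    L = None
    for _ in range(2):
        try:
            L = np.linalg.cholesky(T)
            break
        except np.linalg.LinAlgError:
            T = T + ridge * np.eye(k)
            E = E + ridge * np.eye(k)
    if L is None:
        raise ValidationError("degenerate subset: total scatter is singular")
    Y = solve_triangular(L, E, lower=True)
    C = solve_triangular(L, Y.T, lower=True)
    ev = np.linalg.eigvalsh((C + C.T) / 2.0)
    ev = np.clip(ev, 1e-300, 1.0)
    return float(np.exp(np.log(ev).sum()))


def tau_squared(beta_subset: pd.DataFrame, groups: pd.Series) -> SubsetScore:
    """tau^2 = 1 - Wilks' Lambda of a feature subset for the two-group design."""
    X = beta_subset.to_numpy(dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValidationError("subset must have at least one probe")
    fp, sd = _group_masks(groups, beta_subset.index)
    E, T = _scatter_matrices(X, fp, sd)
    lam = _lambda_from_scatter(E, T)
    lam = min(max(lam, 0.0), 1.0)
    return SubsetScore(
        probe_ids=tuple(beta_subset.columns),
        tau_squared=1.0 - lam,
        wilks_lambda=lam,
    )


def leaps_and_bounds_select(
    beta_candidates: pd.DataFrame,
    groups: pd.Series,
    k: int,
    max_candidates: int = 40,
) -> SubsetScore:
    """Exact best size-``k`` subset by branch and bound on tau^2.

    Because tau^2 never decreases when features are added, the tau^2 of a
    partial selection plus all remaining candidates bounds every completion;
    branches whose bound cannot beat the incumbent are pruned, so the result
    equals exhaustive enumeration. Ties are broken lexicographically by probe
    id.
    """
    m = beta_candidates.shape[1]
    if k > m:
        raise ValidationError(f"k={k} exceeds the {m} candidate probes")
    if m > max_candidates:
        raise ValidationError(
            f"{m} candidates exceed the configured cap of {max_candidates}; "
            "pre-filter by DMP rank first"
        )
    X = beta_candidates.to_numpy(dtype=float)
    fp, sd = _group_masks(groups, beta_candidates.index)
    E_full, T_full = _scatter_matrices(X, fp, sd)
    cols = list(beta_candidates.columns)

    # order candidates by individual tau^2 (descending) to tighten pruning
    singles = [1.0 - _lambda_from_scatter(E_full[[j]][:, [j]], T_full[[j]][:, [j]]) for j in range(m)]
    cand_order = sorted(range(m), key=lambda j: (-singles[j], cols[j]))

    def tau_of(idx: tuple[int, ...]) -> float:
        ix = np.array(idx)
        return 1.0 - _lambda_from_scatter(E_full[np.ix_(ix, ix)], T_full[np.ix_(ix, ix)])

    best = {"tau": -1.0, "ids": None, "idx": None}

    def consider(idx: tuple[int, ...]) -> None:
        tau = tau_of(idx)
        ids = tuple(sorted(cols[j] for j in idx))
        if tau > best["tau"] + 1e-12 or (
            abs(tau - best["tau"]) <= 1e-12 and (best["ids"] is None or ids < best["ids"])
        ):
            best.update(tau=tau, ids=ids, idx=idx)

    def recurse(chosen: tuple[int, ...], pool: list[int]) -> None:
        if len(chosen) == k:
            consider(chosen)
            return
        need = k - len(chosen)
        if len(pool) < need:
            return
        # bound: tau^2 of chosen plus the whole remaining pool
        bound = tau_of(tuple(chosen) + tuple(pool))
        if bound < best["tau"] - 1e-12:
            return
        if bound <= best["tau"] + 1e-12:
            # can only tie: still worth exploring for lexicographic tie-break
            pass
        head, rest = pool[0], pool[1:]
        recurse(chosen + (head,), rest)
        recurse(chosen, rest)

    recurse(tuple(), cand_order)
    assert best["idx"] is not None
    ix = tuple(sorted(best["idx"], key=lambda j: cols[j]))
    return SubsetScore(
        probe_ids=tuple(cols[j] for j in ix),
        tau_squared=float(best["tau"]),
        wilks_lambda=float(1.0 - best["tau"]),
    )


def lda_fit(
    beta_panel: pd.DataFrame,
    groups: pd.Series,
    priors: tuple[float, float] | None = None,
) -> PanelModel:
    """Two-class LDA on the panel probes.

    Weights are w proportional to Sigma_pooled^-1 (mu_FP - mu_SD), scaled so
    the projected pooled within-group variance equals 1 and signed so the FP
    centroid has negative LD1. The decision threshold is the midpoint of the
    projected class means shifted by the log prior ratio.
    """
    X = beta_panel.to_numpy(dtype=float)
    fp, sd = _group_masks(groups, beta_panel.index)
    n_fp, n_sd = int(fp.sum()), int(sd.sum())
    if priors is None:
        priors = (n_fp / (n_fp + n_sd), n_sd / (n_fp + n_sd))
    mu_fp = X[fp].mean(axis=0)
    mu_sd = X[sd].mean(axis=0)
    r_fp = X[fp] - mu_fp
    r_sd = X[sd] - mu_sd
    k = X.shape[1]
    cov = (r_fp.T @ r_fp + r_sd.T @ r_sd) / (n_fp + n_sd - 2)
    tr = np.trace(cov)
    ridge = _RIDGE * (tr / k if tr > 0 else 1.0)
    if np.linalg.cond(cov) > 1e10:
        cov = cov + ridge * np.eye(k)
    w = np.linalg.solve(cov, mu_fp - mu_sd)
    proj_var = float(w @ cov @ w)
    if proj_var <= 0:
        raise ValidationError("degenerate panel: projected variance not positive")
    w = w / np.sqrt(proj_var)
    center = (mu_fp + mu_sd) / 2.0
    m_fp = float(w @ (mu_fp - center))
    m_sd = float(w @ (mu_sd - center))
    if m_fp > m_sd:  # FP goes on the negative side of LD1
        w, m_fp, m_sd = -w, -m_fp, -m_sd
    # posterior-equality point of the two equal-variance Gaussians on LD1
    gap = m_sd - m_fp
    threshold = (m_fp + m_sd) / 2.0
    if gap > 0 and priors[0] > 0 and priors[1] > 0:
        threshold += np.log(priors[0] / priors[1]) / gap
    return PanelModel(
        probe_ids=list(beta_panel.columns),
        weights=w,
        center=center,
        mean_fp=m_fp,
        mean_sd=m_sd,
        priors=priors,
        threshold=float(threshold),
    )


def lda_predict(model: PanelModel, beta_panel: pd.DataFrame) -> pd.DataFrame:
    """Project samples on LD1 and return class probabilities and bands.

    The posterior uses the two-class equal-variance Gaussian discriminant on
    the projected scale. Band "high" means max class probability >= 0.95,
    otherwise "low" (> 0.5).
    """
    missing = [p for p in model.probe_ids if p not in beta_panel.columns]
    if missing:
        raise ValidationError(f"input lacks panel probes: {missing}")
    X = beta_panel.loc[:, model.probe_ids].to_numpy(dtype=float)
    ld1 = (X - model.center) @ model.weights
    log_fp = np.log(model.priors[0]) - 0.5 * (ld1 - model.mean_fp) ** 2
    log_sd = np.log(model.priors[1]) - 0.5 * (ld1 - model.mean_sd) ** 2
    mx = np.maximum(log_fp, log_sd)
    pf = np.exp(log_fp - mx)
    ps = np.exp(log_sd - mx)
    p_fp = pf / (pf + ps)
    p_sd = 1.0 - p_fp
    pred = np.where(p_fp >= p_sd, "FP", "SD")
    maxp = np.maximum(p_fp, p_sd)
    band = np.where(maxp >= 0.95, "high", "low")
    return pd.DataFrame(
        {
            "sample_id": beta_panel.index,
            "ld1": ld1,
            "p_fp": p_fp,
            "p_sd": p_sd,
            "predicted": pred,
            "band": band,
        }
    ).set_index("sample_id")


def minimal_panel(
    beta_candidates: pd.DataFrame,
    groups: pd.Series,
    k_max: int,
    priors: tuple[float, float] | None = None,
    max_candidates: int = 40,
) -> PanelModel:
    """Smallest panel achieving zero training misclassifications.

    For k = 1..k_max the exact best tau^2 subset is selected and an LDA model
    fitted; the first k with perfect training classification wins (models
    needing fewer input features are preferred). If no panel separates, the
    k_max model is returned flagged ``non_separating``.
    """
    if k_max > beta_candidates.shape[1]:
        raise ValidationError("k_max exceeds the candidate count")
    groups = pd.Series(groups).loc[beta_candidates.index]
    model = None
    for k in range(1, k_max + 1):
        score = leaps_and_bounds_select(
            beta_candidates, groups, k, max_candidates=max_candidates
        )
        sub = beta_candidates.loc[:, list(score.probe_ids)]
        model = lda_fit(sub, groups, priors=priors)
        model.tau_squared = score.tau_squared
        preds = lda_predict(model, sub)["predicted"]
        if (preds == groups).all():
            return model
    assert model is not None
    model.non_separating = True
    return model


def repeated_cv(
    beta_candidates: pd.DataFrame,
    groups: pd.Series,
    folds: int = 5,
    repeats: int = 10,
    k_max: int = 6,
    seed: int = 0,
    max_candidates: int = 40,
) -> dict:
    """Stratified five-fold repeated CV of the full selection + LDA procedure.

    Panel selection and model fitting are redone inside every training fold
    (no leakage from held-out samples into selection). Returns per-repeat
    held-out accuracies and their mean.
    """
    groups = pd.Series(groups).loc[beta_candidates.index]
    class_sizes = groups.value_counts()
    if (class_sizes < folds).any():
        raise ValidationError(
            f"each class needs >= {folds} samples for {folds}-fold stratification; "
            f"sizes: {class_sizes.to_dict()}"
        )
    rng = np.random.default_rng(seed)
    accuracies = []
    y = groups.to_numpy()
    for _ in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        correct = 0
        for train_idx, test_idx in skf.split(beta_candidates, y):
            train = beta_candidates.iloc[train_idx]
            test = beta_candidates.iloc[test_idx]
            model = minimal_panel(
                train, groups.iloc[train_idx], k_max, max_candidates=max_candidates
            )
            preds = lda_predict(model, test)["predicted"]
            correct += int((preds.to_numpy() == y[test_idx]).sum())
        accuracies.append(correct / len(y))
    return {"accuracies": np.array(accuracies), "mean_accuracy": float(np.mean(accuracies))}
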