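"""Pipeline driver: configuration, stage ordering and run outputs.

Stage order: detection-p filtering -> BMIQ -> {SVD confounder screen, ComBat
for the statistics branch} -> DMPs -> DMRs -> enrichment -> clustering ->
panel selection (on the NON-batch-corrected branch) -> train/test
classification -> epigenetic age -> CNA -> cohort report. Every run directory
records the effective configuration, the seed, a config hash and one log line
per stage with input/output dimensions so filter effects are auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .cna import cna_profile
from .cohortstats import count_methylation_extremes
from .datatypes import BetaMatrix, ValidationError, check_alignment
from .differential import cluster_heatmap_order, find_dmrs, fit_dmp
from .epiage import compute_epigenetic_age, ea_ca_contingency, group_age_difference, read_clock
from .panel import lda_predict, minimal_panel
from .preprocess import bmiq_normalize, combat_correct, filter_by_detection, svd_confounder_screen

log = logging.getLogger("pmfmeth")


@dataclass
class PipelineConfig:
    """All stage parameters; unknown keys in a config file are rejected."""

    beta: str = "beta.tsv"
    detp: str = "detp.tsv"
    meth: str = ""
    unmeth: str = ""
    manifest: str = "manifest.csv"
    samples: str = "samples.csv"
    clock: str = ""
    out: str = "run"
    seed: int = 0
    # filtering
    p_thresh: float = 0.1
    probe_fail_frac: float = 0.05
    sample_fail_frac: float = 0.1
    # normalization
    bmiq_min_per_type: int = 100
    skip_bmiq: bool = False
    # batch correction
    batch_column: str = "plate"
    skip_combat: bool = False
    # differential
    dmp_fdr: float = 0.1
    dmr_max_gap: int = 250
    dmr_cutoff_quantile: float = 0.99
    dmr_n_perm: int = 250
    dmr_fdr: float = 0.05
    cluster_top_n: int = 25
    # panel
    candidate_pool: int = 40
    k_max: int = 6
    cv_folds: int = 5
    cv_repeats: int = 0
    test_samples: list[str] = field(default_factory=list)
    # CNA
    cna_min_probes: int = 10
    cna_alpha: float = 0.01
    cna_threshold: float = 0.5
    # extremes
    hi_threshold: float = 0.8
    lo_threshold: float = 0.1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _stage(name: str, msg: str) -> None:
    log.info("[%s] %s", name, msg)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages on the configured inputs; returns the run directory."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> Path:
    (out / "config.yaml").write_text(
        yaml.safe_dump({**config.to_dict(), "config_hash": config.config_hash()})
    )
    beta = pio.read_beta_matrix(config.beta)
    detp = pio.read_matrix(config.detp)
    manifest = pio.read_manifest(config.manifest)
    sheet = pio.read_sample_sheet(config.samples)
    check_alignment(beta, manifest, sheet)
    groups_all = sheet.groups

    # upfront validation that fails before any compute
    train_ids = [s for s in beta.sample_ids if s not in set(config.test_samples)]
    if config.cv_repeats > 0:
        sizes = groups_all.loc[train_ids].value_counts()
        if (sizes < config.cv_folds).any():
            raise ValidationError(
                f"cannot stratify {config.cv_folds} folds with class sizes "
                f"{sizes.to_dict()}"
            )
    _stage("load", f"{beta.shape[0]} samples x {beta.shape[1]} probes")

    # --- filtering -----------------------------------------------------------
    beta, report = filter_by_detection(
        beta,
        detp,
        p_thresh=config.p_thresh,
        probe_fail_frac=config.probe_fail_frac,
        sample_fail_frac=config.sample_fail_frac,
    )
    (out / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=1))
    _stage("filter", f"-> {beta.shape[0]} samples x {report.n_evaluable} probes")

    # --- BMIQ ---------------------------------------------------------------
    if not config.skip_bmiq:
        design = manifest.for_probes(beta.probe_ids)["design_type"]
        vals = beta.values
        for i in range(vals.shape[0]):
            vals[i] = bmiq_normalize(vals[i], design, min_per_type=config.bmiq_min_per_type)
        beta = BetaMatrix(pd.DataFrame(vals, index=beta.sample_ids, columns=beta.probe_ids))
        _stage("bmiq", f"normalized {vals.shape[0]} samples")

    groups = groups_all.loc[beta.sample_ids]
    sheet_df = sheet.df.loc[beta.sample_ids]

    # --- SVD screen and ComBat (statistics branch only) ----------------------
    screen_vars = [c for c in ("plate", "age", "sex") if c in sheet_df.columns]
    screen = svd_confounder_screen(beta, sheet_df[screen_vars])
    screen.to_csv(out / "svd_screen.tsv", sep="\t", index=False)
    _stage("svd", f"screened {len(screen_vars)} variables")

    if not config.skip_combat and sheet_df[config.batch_column].nunique() > 1:
        beta_stats = combat_correct(
            beta, sheet_df[config.batch_column], covariates=sheet_df[["group"]]
        )
        _stage("combat", f"corrected batches: {sorted(sheet_df[config.batch_column].unique())}")
    else:
        beta_stats = beta
        _stage("combat", "skipped")
    pio.write_matrix(beta_stats.df, out / "beta_corrected.tsv")

    # --- differential methylation -------------------------------------------
    dmps = fit_dmp(beta_stats, groups)
    pio.write_dmp_table(dmps, out / "dmps.tsv")
    n_sig = int((dmps["q"] <= config.dmp_fdr).sum())
    _stage("dmp", f"{n_sig} DMPs at q <= {config.dmp_fdr}")

    dmrs = find_dmrs(
        beta_stats,
        groups,
        manifest,
        max_gap=config.dmr_max_gap,
        cutoff_quantile=config.dmr_cutoff_quantile,
        n_perm=config.dmr_n_perm,
        fdr=config.dmr_fdr,
        seed=config.seed,
    )
    pio.write_dmr_table(dmrs, out / "dmrs.tsv")
    pio.write_dmr_bed(dmrs, out / "dmrs.bed")
    _stage("dmr", f"{len(dmrs)} DMRs at q <= {config.dmr_fdr}")

    # --- clustering -----------------------------------------------------------
    top_n = min(config.cluster_top_n, len(dmps))
    if top_n >= 2:
        probe_order, sample_order, _ = cluster_heatmap_order(beta_stats, dmps, top_n)
        (out / "cluster_order.json").write_text(
            json.dumps({"probes": probe_order, "samples": sample_order}, indent=1)
        )
        _stage("cluster", f"ordered top {top_n} probes")

    # --- panel selection on the non-corrected branch --------------------------
    candidates = dmps["probe_id"].head(config.candidate_pool).tolist()
    train_ids = [s for s in beta.sample_ids if s not in set(config.test_samples)]
    train = beta.df.loc[train_ids, candidates]
    model = minimal_panel(
        train,
        groups.loc[train_ids],
        k_max=config.k_max,
        max_candidates=config.candidate_pool,
    )
    model.to_json(out / "panel.json")
    preds_train = lda_predict(model, train)
    preds_train.to_csv(out / "predictions_train.tsv", sep="\t")
    train_acc = float((preds_train["predicted"] == groups.loc[train_ids]).mean())
    results = {
        "panel_size": len(model.probe_ids),
        "panel_probes": model.probe_ids,
        "non_separating": model.non_separating,
        "train_accuracy": train_acc,
    }
    _stage("panel", f"size {len(model.probe_ids)}, train accuracy {train_acc:.3f}")

    test_ids = [s for s in config.test_samples if s in beta.df.index]
    if test_ids:
        test = beta.df.loc[test_ids, candidates]
        preds_test = lda_predict(model, test)
        preds_test.to_csv(out / "predictions_test.tsv", sep="\t")
        test_acc = float((preds_test["predicted"] == groups.loc[test_ids]).mean())
        results["test_accuracy"] = test_acc
        _stage("classify", f"test accuracy {test_acc:.3f} on {len(test_ids)} samples")

    # --- epigenetic age -------------------------------------------------------
    if config.clock:
        clock = read_clock(config.clock)
        ages = compute_epigenetic_age(beta, clock, ages=sheet_df["age"])
        ages.to_csv(out / "epigenetic_age.tsv", sep="\t")
        tab, chi2, p = ea_ca_contingency(ages, groups)
        diff = group_age_difference(ages, groups)
        results["epiage"] = {
            "contingency": tab.to_dict(),
            "chi2": chi2,
            "chi2_p": p,
            "group_difference": diff,
        }
        _stage("epiage", f"EA>CA chi2 p = {p:.4g}")

    # --- CNA ------------------------------------------------------------------
    if config.meth and config.unmeth:
        meth = pio.read_matrix(config.meth)
        unmeth = pio.read_matrix(config.unmeth)
        fp_ids = [s for s in beta.sample_ids if groups.loc[s] == "FP"]
        sd_ids = [s for s in beta.sample_ids if groups.loc[s] == "SD"]
        profile = cna_profile(
            meth.loc[beta.sample_ids, beta.probe_ids],
            unmeth.loc[beta.sample_ids, beta.probe_ids],
            manifest,
            query_samples=fp_ids,
            reference_samples=sd_ids,
            min_probes=config.cna_min_probes,
            alpha=config.cna_alpha,
            threshold=config.cna_threshold,
        )
        profile.to_seg("FP_median", out / "cna_segments.seg")
        n_calls = sum(1 for s in profile.segments if s.call != "neutral")
        results["cna_calls"] = n_calls
        _stage("cna", f"{len(profile.segments)} segments, {n_calls} gain/loss calls")

    # --- cohort report --------------------------------------------------------
    extremes = count_methylation_extremes(
        beta, groups, hi=config.hi_threshold, lo=config.lo_threshold
    )
    results["extremes"] = {
        "count_high": extremes.count_high,
        "count_low": extremes.count_low,
        "pct_difference_high": extremes.percent_difference_high(),
        "pct_difference_low": extremes.percent_difference_low(),
    }
    results["n_evaluable"] = report.n_evaluable
    results["seed"] = config.seed
    results["config_hash"] = config.config_hash()
    (out / "report.json").write_text(json.dumps(results, indent=1))
    _stage("report", "written report.json")
    return out
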