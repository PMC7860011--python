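"""Synthetic EPIC-style methylation cohorts with known planted structure.

The generator emulates the statistical features of a two-group (fibrotic
progression vs stable disease) bone-marrow methylation study so that every
downstream stage of the pipeline can be checked against ground truth:

* bimodal beta-value distributions, with the type II Infinium design showing a
  compressed dynamic range relative to type I (the distortion BMIQ corrects);
* planted group effects at chosen CpGs (DMPs) and at clustered runs of CpGs
  (DMRs) on the beta scale;
* plate batch effects applied on the logit (M-value) scale;
* probe failures expressed through inflated detection p-values;
* copy-number segments as multiplicative shifts of both intensity channels;
* an age-linear clock signal at a dedicated probe set.

Within-probe biological/technical noise is drawn on the M-value scale
(logit-normal beta), which is the Gaussian modelling scale assumed by the
linear models downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    BetaMatrix,
    ClockModel,
    ProbeAnnotation,
    SampleSheet,
    ValidationError,
    inv_logit_m,
    logit_clamped,
)

AUTOSOMES = [f"chr{i}" for i in range(1, 23)]

# Beta-mixture used for baseline probe means: (weight, a, b) per methylation
# state (unmethylated / hemimethylated / methylated), matching the 3-state
# model BMIQ assumes.
_STATE_WEIGHTS = (0.42, 0.14, 0.44)
_STATE_PARAMS = ((6.0, 54.0), (40.0, 40.0), (54.0, 6.0))
# Type II probes read a compressed dynamic range: means shrunk toward 0.5.
_TYPE2_COMPRESSION = 0.75

_ISLAND_PROBS = {
    "Island": 0.31,
    "N_Shore": 0.12,
    "S_Shore": 0.12,
    "N_Shelf": 0.05,
    "S_Shelf": 0.05,
    "OpenSea": 0.35,
}


@dataclass
class DmpSpec:
    """A set of probe indices that receive a group effect of ``delta_beta``."""

    probes: tuple[int, ...]
    delta_beta: float


@dataclass
class DmrSpec:
    """A clustered run of probes forming a differentially methylated region."""

    chrom: str
    start: int
    n_probes: int
    spacing: int
    delta_beta: float


@dataclass
class CnaSpec:
    """A copy-number segment: intensity shift 2**log2_shift for a sample subset."""

    samples: tuple[int, ...]
    chrom: str
    start: int
    end: int
    log2_shift: float


@dataclass
class PanelSpec:
    """A planted minimal classifier signature.

    The probes carry a group effect of alternating sign (+delta for even
    positions in ``probes``, -delta for odd ones) plus a shared per-sample
    latent factor (think cellular-composition or subclone fraction). The
    first ``n_excursions`` samples of each group carry latent excursions of
    alternating sign and magnitude ``delta_beta``, which puts each of them at
    the opposite class centroid on every single panel probe: no single probe
    (nor a planted probe paired with a noise probe) can separate the groups.
    Because the latent factor enters all panel probes identically, the
    difference of a hyper/hypo probe pair cancels it exactly, so the smallest
    perfectly separating panel is a pair: the planted minimal panel size is 2.
    """

    probes: tuple[int, ...]
    delta_beta: float = 0.28
    base: float = 0.5
    latent_sd: float = 0.03  # residual shared-factor spread
    n_excursions: int = 2  # per group; alternating +delta / -delta
    noise_sd: float = 0.012  # independent per-probe beta noise

    @property
    def minimal_size(self) -> int:
        return 2 if len(self.probes) >= 2 else 1


@dataclass
class ClockSpec:
    """An age-linear probe set: beta rises linearly with chronological age."""

    probes: tuple[int, ...]
    weight: float = 5.0  # years of epigenetic age per unit beta, per probe
    intercept: float = 0.0  # years
    noise_sd: float = 2.0  # years, on the recovered epigenetic age


@dataclass
class SimConfig:
    """Full description of a synthetic cohort; identical config + seed gives
    bit-identical output."""

    n_fp: int = 16
    n_sd: int = 17
    n_probes: int = 10_000
    n_plates: int = 2
    dmp_spec: list[DmpSpec] = field(default_factory=list)
    dmr_spec: list[DmrSpec] = field(default_factory=list)
    cna_spec: list[CnaSpec] = field(default_factory=list)
    panel_spec: PanelSpec | None = None
    clock_spec: ClockSpec | None = None
    batch_effect_sd: float = 0.0  # logit-scale sd of per-(plate, probe) shifts
    probe_fail_rate: float = 0.002  # per-sample fraction of failing probes
    noise_sd_m: float = 0.25  # within-probe M-value sd
    mean_intensity: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_fp", "n_sd", "n_probes", "n_plates"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not 0.0 <= self.probe_fail_rate <= 1.0:
            raise ValidationError("probe_fail_rate must lie in [0, 1]")
        for spec in self.dmp_spec:
            if abs(spec.delta_beta) > 1:
                raise ValidationError("delta_beta must lie in [-1, 1]")
        self._planted_probe_sets()  # raises on collisions / range errors

    def _planted_probe_sets(self) -> dict[str, set[int]]:
        """Validate disjointness of planted probe sets and return them."""
        sets: dict[str, set[int]] = {}
        for i, spec in enumerate(self.dmp_spec):
            sets[f"dmp[{i}]"] = set(spec.probes)
        # DMR probe indices are allocated deterministically (see generate_cohort):
        # consecutive blocks from the top of the index range.
        offset = self.n_probes
        for i, spec in enumerate(self.dmr_spec):
            offset -= spec.n_probes
            sets[f"dmr[{i}]"] = set(range(offset, offset + spec.n_probes))
        if self.panel_spec is not None:
            sets["panel"] = set(self.panel_spec.probes)
        if self.clock_spec is not None:
            sets["clock"] = set(self.clock_spec.probes)
        seen: dict[int, str] = {}
        for name, probes in sets.items():
            for p in probes:
                if p < 0 or p >= self.n_probes:
                    raise ValidationError(f"planted probe index {p} in {name} out of range")
                if p in seen:
                    raise ValidationError(
                        f"planted probe sets overlap: probe {p} in both {seen[p]} and {name}"
                    )
                seen[p] = name
        return sets


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth of everything planted in it."""

    beta: BetaMatrix
    meth: pd.DataFrame
    unmeth: pd.DataFrame
    detection_p: pd.DataFrame
    annotation: ProbeAnnotation
    samples: SampleSheet
    truth: dict
    clock: ClockModel | None = None


def _dmr_probe_indices(config: SimConfig) -> list[tuple[DmrSpec, list[int]]]:
    out = []
    offset = config.n_probes
    for spec in config.dmr_spec:
        offset -= spec.n_probes
        out.append((spec, list(range(offset, offset + spec.n_probes))))
    return out


def _build_manifest(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_probes
    probe_ids = [f"cg{i:08d}" for i in range(n)]
    # Regular probes: contiguous per-chromosome blocks, uniform 5 kb spacing.
    per_chrom = int(np.ceil(n / len(AUTOSOMES)))
    chroms = np.repeat(AUTOSOMES, per_chrom)[:n]
    pos = np.zeros(n, dtype=int)
    for c in AUTOSOMES:
        idx = np.where(chroms == c)[0]
        pos[idx] = 1_000_000 + 5_000 * np.arange(idx.size)
    # DMR clusters override geometry: configured spacing below maxGap.
    chroms = chroms.astype(object)
    for spec, idxs in _dmr_probe_indices(config):
        for j, p in enumerate(idxs):
            chroms[p] = spec.chrom
            pos[p] = spec.start + j * spec.spacing
    design = rng.choice(["I", "II"], size=n, p=[0.35, 0.65])
    island = rng.choice(list(_ISLAND_PROBS), size=n, p=list(_ISLAND_PROBS.values()))
    # Genes cover blocks of neighbouring probes (variable probe counts per
    # gene feed the enrichment bias model); ~1/3 of probes are intergenic.
    gene = np.array([f"GENE{i // 8}" for i in range(n)], dtype=object)
    gene[rng.random(n) < 0.33] = ""
    df = pd.DataFrame(
        {
            "chr": chroms,
            "pos": pos,
            "design_type": design,
            "island_relation": island,
            "gene": gene,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return df


def _build_sample_sheet(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids = [f"FP{i + 1:02d}" for i in range(config.n_fp)] + [
        f"SD{i + 1:02d}" for i in range(config.n_sd)
    ]
    group = ["FP"] * config.n_fp + ["SD"] * config.n_sd
    # plates alternate within each group so batch is never confounded with group
    plate = [f"plate{(i % config.n_plates) + 1}" for i in range(config.n_fp)] + [
        f"plate{(i % config.n_plates) + 1}" for i in range(config.n_sd)
    ]
    age = np.concatenate(
        [
            np.clip(rng.normal(62.0, 9.0, config.n_fp), 30, 88),
            np.clip(rng.normal(56.0, 9.0, config.n_sd), 30, 88),
        ]
    ).round(1)
    sex = rng.choice(["F", "M"], size=len(ids), p=[0.45, 0.55])
    hmr = np.concatenate(
        [
            rng.random(config.n_fp) < 0.44,
            rng.random(config.n_sd) < 0.05,
        ]
    ).astype(int)
    leukocytes = np.round(rng.lognormal(np.log(12.0), 0.5, len(ids)), 1)
    platelets = np.round(rng.lognormal(np.log(800.0), 0.35, len(ids)), 0)
    hemoglobin = np.round(rng.normal(13.0, 1.8, len(ids)), 1)
    return pd.DataFrame(
        {
            "group": group,
            "plate": plate,
            "age": age,
            "sex": sex,
            "hmr": hmr,
            "leukocytes": leukocytes,
            "platelets": platelets,
            "hemoglobin": hemoglobin,
        },
        index=pd.Index(ids, name="sample_id"),
    )


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a complete synthetic cohort from ``config``.

    Returns beta-values, both intensity channels, detection p-values, the
    probe manifest, the sample sheet and a ``truth`` record of all planted
    structure. Deterministic given ``config`` (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    manifest = _build_manifest(config, rng)
    sheet = _build_sample_sheet(config, rng)
    n_samples = len(sheet)
    n = config.n_probes
    is_fp = (sheet["group"] == "FP").to_numpy()

    # --- baseline probe means from the 3-state beta mixture -----------------
    state = rng.choice(3, size=n, p=_STATE_WEIGHTS)
    mu = np.empty(n)
    for s, (a, b) in enumerate(_STATE_PARAMS):
        idx = state == s
        mu[idx] = rng.beta(a, b, idx.sum())
    type2 = (manifest["design_type"] == "II").to_numpy()
    mu[type2] = 0.5 + _TYPE2_COMPRESSION * (mu[type2] - 0.5)

    # --- per-sample beta: logit-normal noise around the probe mean ----------
    m = logit_clamped(mu)[None, :] + rng.normal(0.0, config.noise_sd_m, (n_samples, n))

    # plate effects on the logit scale
    plates = sheet["plate"].to_numpy()
    plate_shift = {}
    if config.batch_effect_sd > 0:
        for p in np.unique(plates):
            plate_shift[p] = rng.normal(0.0, config.batch_effect_sd, n)
        for i, p in enumerate(plates):
            m[i] += plate_shift[p]

    beta = inv_logit_m(m)

    # --- planted group effects on the beta scale -----------------------------
    truth_dmps = []
    for spec in config.dmp_spec:
        idx = np.asarray(spec.probes, dtype=int)
        beta[np.ix_(is_fp, idx)] += spec.delta_beta
        truth_dmps.append({"probes": [int(p) for p in idx], "delta_beta": spec.delta_beta})
    truth_dmrs = []
    for spec, idxs in _dmr_probe_indices(config):
        idx = np.asarray(idxs, dtype=int)
        beta[np.ix_(is_fp, idx)] += spec.delta_beta
        truth_dmrs.append(
            {
                "chrom": spec.chrom,
                "start": spec.start,
                "spacing": spec.spacing,
                "probes": [int(p) for p in idx],
                "delta_beta": spec.delta_beta,
            }
        )

    # --- planted minimal-panel signature -------------------------------------
    truth_panel = None
    if config.panel_spec is not None:
        ps = config.panel_spec
        idx = np.asarray(ps.probes, dtype=int)
        latent = rng.normal(0.0, ps.latent_sd, n_samples)
        # alternating +/- delta excursions on the first samples of each group
        for start in (0, config.n_fp):
            for j in range(min(ps.n_excursions, config.n_fp if start == 0 else config.n_sd)):
                latent[start + j] += ps.delta_beta * (1.0 if j % 2 == 0 else -1.0)
        signs = np.array([1.0 if j % 2 == 0 else -1.0 for j in range(idx.size)])
        for j, p in enumerate(idx):
            # the latent factor enters every panel probe with the same sign,
            # so the hyper/hypo probe difference cancels it exactly
            beta[:, p] = (
                ps.base
                + signs[j] * ps.delta_beta * (is_fp.astype(float) - 0.5)
                + latent
                + rng.normal(0.0, ps.noise_sd, n_samples)
            )
        truth_panel = {
            "probes": [int(p) for p in idx],
            "signs": [float(s) for s in signs],
            "delta_beta": ps.delta_beta,
            "minimal_size": ps.minimal_size,
        }

    # --- clock probes: beta linear in chronological age ----------------------
    clock_model = None
    truth_clock = None
    if config.clock_spec is not None:
        cs = config.clock_spec
        idx = np.asarray(cs.probes, dtype=int)
        k = idx.size
        ages = sheet["age"].to_numpy(dtype=float)
        slope = 1.0 / (k * cs.weight)
        sd_beta = cs.noise_sd / (cs.weight * np.sqrt(k))
        beta[:, idx] = (ages[:, None] - cs.intercept) * slope + rng.normal(
            0.0, sd_beta, (n_samples, k)
        )
        probe_ids = manifest.index.to_numpy()
        clock_model = ClockModel(
            intercept=cs.intercept,
            weights={str(probe_ids[p]): cs.weight for p in idx},
            name="synthetic-clock",
        )
        truth_clock = {
            "probes": [int(p) for p in idx],
            "weight": cs.weight,
            "intercept": cs.intercept,
            "noise_sd": cs.noise_sd,
        }

    beta = np.clip(beta, 0.0, 1.0)

    # --- intensities ---------------------------------------------------------
    base_intensity = rng.lognormal(np.log(config.mean_intensity), 0.3, n)
    sample_gain = rng.lognormal(0.0, 0.1, n_samples)
    total = base_intensity[None, :] * sample_gain[:, None]
    truth_cnas = []
    pos = manifest["pos"].to_numpy()
    chroms = manifest["chr"].to_numpy()
    for spec in config.cna_spec:
        in_seg = (chroms == spec.chrom) & (pos >= spec.start) & (pos <= spec.end)
        for s in spec.samples:
            total[s, in_seg] *= 2.0 ** spec.log2_shift
        truth_cnas.append(
            {
                "samples": [int(s) for s in spec.samples],
                "chrom": spec.chrom,
                "start": spec.start,
                "end": spec.end,
                "log2_shift": spec.log2_shift,
                "n_probes": int(in_seg.sum()),
            }
        )
    meth = beta * total
    unmeth = (1.0 - beta) * total

    # --- detection p-values --------------------------------------------------
    detp = rng.uniform(0.0, 0.01, (n_samples, n))
    failed = rng.random((n_samples, n)) < config.probe_fail_rate
    detp[failed] = rng.uniform(0.15, 1.0, int(failed.sum()))

    probe_ids = list(manifest.index)
    sample_ids = list(sheet.index)
    beta_df = pd.DataFrame(beta, index=sample_ids, columns=probe_ids)
    truth = {
        "dmps": truth_dmps,
        "dmrs": truth_dmrs,
        "cnas": truth_cnas,
        "panel": truth_panel,
        "clock": truth_clock,
        "failed": {
            sample_ids[i]: [int(j) for j in np.where(failed[i])[0]]
            for i in range(n_samples)
            if failed[i].any()
        },
        "seed": config.seed,
    }
    return SyntheticCohort(
        beta=BetaMatrix(beta_df),
        meth=pd.DataFrame(meth, index=sample_ids, columns=probe_ids),
        unmeth=pd.DataFrame(unmeth, index=sample_ids, columns=probe_ids),
        detection_p=pd.DataFrame(detp, index=sample_ids, columns=probe_ids),
        annotation=ProbeAnnotation(manifest),
        samples=SampleSheet(sheet),
        truth=truth,
        clock=clock_model,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write a cohort as the pipeline's delimited input files plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.beta.df.to_csv(out / "beta.tsv", sep="\t", index_label="sample_id")
    cohort.meth.to_csv(out / "meth.tsv", sep="\t", index_label="sample_id")
    cohort.unmeth.to_csv(out / "unmeth.tsv", sep="\t", index_label="sample_id")
    cohort.detection_p.to_csv(out / "detp.tsv", sep="\t", index_label="sample_id")
    cohort.annotation.df.to_csv(out / "manifest.csv", index_label="probe_id")
    cohort.samples.df.to_csv(out / "samples.csv", index_label="sample_id")
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    if cohort.clock is not None:
        rows = [("intercept", cohort.clock.intercept)] + list(cohort.clock.weights.items())
        pd.DataFrame(rows, columns=["probe_id", "weight"]).to_csv(
            out / "clock.csv", index=False
        )
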