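"""Core in-memory containers shared across the pipeline.

The array data model follows the Illumina Infinium convention: a cohort is a
samples x probes matrix of methylation fractions (beta-values) in [0, 1],
accompanied by a probe manifest (genomic coordinates, Infinium design type,
CpG-island relation, associated gene) and a sample sheet (group label,
plate/batch, chronological age, sex, optional clinical covariates).
Missing measurements are represented as NaN inside the beta matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ISLAND_VOCABULARY = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
GROUPS = ("FP", "SD")


class ValidationError(ValueError):
    """Raised when an input object violates its documented invariants."""


@dataclass
class BetaMatrix:
    """Samples x probes matrix of beta-values with NaN as missing-value mask.

    Parameters
    ----------
    df:
        DataFrame indexed by sample id with probe ids as columns. All
        non-missing entries must lie in [0, 1]; both axes must carry unique
        labels.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.df.index.is_unique:
            raise ValidationError("duplicate sample ids in beta matrix")
        if not self.df.columns.is_unique:
            raise ValidationError("duplicate probe ids in beta matrix")
        vals = self.df.to_numpy(dtype=float)
        bad = np.where((vals < 0) | (vals > 1))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"beta value {vals[i, j]:g} outside [0, 1] at "
                f"(sample={self.df.index[i]!r}, probe={self.df.columns[j]!r})"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the measurement is missing."""
        return np.isnan(self.values)

    def select_probes(self, probes: Iterable[str]) -> "BetaMatrix":
        return BetaMatrix(self.df.loc[:, list(probes)])

    def select_samples(self, samples: Iterable[str]) -> "BetaMatrix":
        return BetaMatrix(self.df.loc[list(samples)])

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape


@dataclass
class ProbeAnnotation:
    """Per-probe manifest: coordinates (1-based), design type, island relation, gene."""

    df: pd.DataFrame

    REQUIRED = ("chr", "pos", "design_type", "island_relation", "gene")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        if not self.df.index.is_unique:
            raise ValidationError("duplicate probe ids in manifest")
        bad_design = set(self.df["design_type"]) - {"I", "II"}
        if bad_design:
            raise ValidationError(f"unknown design types: {sorted(bad_design)}")
        bad_island = set(self.df["island_relation"]) - set(ISLAND_VOCABULARY)
        if bad_island:
            raise ValidationError(f"unknown island relations: {sorted(bad_island)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.df.index)

    def for_probes(self, probes: Iterable[str]) -> pd.DataFrame:
        return self.df.loc[list(probes)]


@dataclass
class SampleSheet:
    """Sample metadata: group (FP/SD), plate, age, sex and optional clinical columns."""

    df: pd.DataFrame

    REQUIRED = ("group", "plate", "age", "sex")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        if not self.df.index.is_unique:
            raise ValidationError("duplicate sample ids in sample sheet")
        bad = set(self.df["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)} (expected FP/SD)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def groups(self) -> pd.Series:
        return self.df["group"]


@dataclass
class FilterReport:
    """Outcome of detection-p-value quality filtering."""

    excluded_samples: dict[str, float]  # sample id -> fraction of failed probes
    excluded_probes: dict[str, str]  # probe id -> reason
    n_evaluable: int

    def to_dict(self) -> dict:
        return {
            "excluded_samples": self.excluded_samples,
            "excluded_probes": self.excluded_probes,
            "n_evaluable": self.n_evaluable,
        }


@dataclass
class ClockModel:
    """Linear epigenetic clock: age = intercept + sum_i weight_i * beta_i (years)."""

    intercept: float
    weights: Mapping[str, float]
    name: str = "clock"

    def __post_init__(self) -> None:
        if len(self.weights) == 0:
            raise ValidationError("clock model needs at least one probe weight")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.weights)


@dataclass
class AgeResult:
    """Per-sample epigenetic age (EA), chronological age (CA) and their difference."""

    sample_id: str
    ea: float
    ca: float

    @property
    def delta(self) -> float:
        return self.ea - self.ca


def check_alignment(
    beta: BetaMatrix,
    annotation: ProbeAnnotation | None = None,
    samples: SampleSheet | None = None,
) -> None:
    """Cross-check that probe and sample ids agree across the input files."""
    if annotation is not None:
        b, a = set(beta.probe_ids), set(annotation.probe_ids)
        if b != a:
            diff = sorted(b.symmetric_difference(a))
            raise ValidationError(
                f"probe ids differ between beta matrix and manifest; "
                f"symmetric difference (first 10): {diff[:10]} ({len(diff)} total)"
            )
    if samples is not None:
        b, s = set(beta.sample_ids), set(samples.sample_ids)
        if b != s:
            diff = sorted(b.symmetric_difference(s))
            raise ValidationError(
                f"sample ids differ between beta matrix and sample sheet; "
                f"symmetric difference (first 10): {diff[:10]} ({len(diff)} total)"
            )


def logit_clamped(beta: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Beta -> M-value transform with clamping to [eps, 1-eps] before the logit.

    The clamp keeps the transform bounded; the induced bias is negligible for
    the array-typical eps of 1e-3.
    """
    b = np.clip(beta, eps, 1.0 - eps)
    return np.log2(b / (1.0 - b))


def inv_logit_m(m: np.ndarray) -> np.ndarray:
    """M-value -> beta transform (base-2 logistic)."""
    return 1.0 / (1.0 + np.power(2.0, -np.asarray(m, dtype=float)))
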