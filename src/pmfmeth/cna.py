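"""Copy-number profiles from methylation-array intensities.

Combined methylated + unmethylated signal intensity is proportional to local
DNA copy number, so a query sample (or the median profile of a query group)
can be compared against a reference cohort: per-probe log2 copy ratios are
taken against the probe-wise reference median, recentred so each profile's
median autosomal ratio is zero (whole-genome ploidy is unobservable), and
segmented by recursive binary splitting. Segments whose mean |log2 ratio|
reaches the call threshold (default 0.5) are reported as gains or losses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ProbeAnnotation, ValidationError


@dataclass
class Segment:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    n_probes: int
    seg_log2: float
    call: str = "neutral"


@dataclass
class CNAProfile:
    """Per-probe log2 ratios plus segments and gain/loss calls."""

    probes: pd.DataFrame  # columns: chr, pos, log2_ratio
    segments: list[Segment] = field(default_factory=list)

    def to_seg(self, sample_id: str, path: str | Path) -> None:
        """Write segments in SEG format (1-based coordinates)."""
        rows = [
            (sample_id, s.chrom, s.start, s.end, s.n_probes, round(s.seg_log2, 6))
            for s in self.segments
        ]
        pd.DataFrame(
            rows, columns=["sample", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
        ).to_csv(path, sep="\t", index=False)


def combined_intensity(meth: pd.DataFrame, unmeth: pd.DataFrame) -> pd.DataFrame:
    """Total per-probe signal: methylated + unmethylated channel."""
    if meth.shape != unmeth.shape:
        raise ValidationError("intensity matrices are not conformal")
    if (meth.to_numpy() < 0).any() or (unmeth.to_numpy() < 0).any():
        raise ValidationError("negative intensity encountered")
    return meth + unmeth.loc[meth.index, meth.columns]


def log2_ratio(
    sample_total: pd.Series,
    reference_totals: pd.DataFrame,
) -> pd.Series:
    """Per-probe log2 ratio of a sample against the reference probe medians.

    The profile is recentred so its median (autosomal) log2 ratio is zero;
    probes with a non-positive reference median are dropped with a warning.
    """
    if reference_totals.shape[0] < 3:
        raise ValidationError("need >= 3 reference samples")
    ref_med = reference_totals.median(axis=0)
    common = sample_total.index.intersection(ref_med.index)
    s = sample_total.loc[common].astype(float)
    r = ref_med.loc[common].astype(float)
    ok = (r > 0) & (s > 0)
    if (~ok).any():
        warnings.warn(
            f"dropped {int((~ok).sum())} probe(s) with non-positive intensity",
            stacklevel=2,
        )
    ratio = np.log2(s[ok] / r[ok])
    return ratio - ratio.median()


def segment_profile(
    ratios: pd.Series,
    annotation: ProbeAnnotation,
    min_probes: int = 10,
    alpha: float = 0.01,
) -> list[Segment]:
    """Recursive binary segmentation of a log2-ratio profile per chromosome.

    Each chromosome is split at the position maximising the two-sample
    t-statistic between the flanks; a split is accepted when its p-value is
    below ``alpha`` and both sides keep >= ``min_probes`` probes. Segment
    value = mean ratio of its probes (probe means are conserved exactly).
    """
    ann = annotation.for_probes(ratios.index)
    df = pd.DataFrame(
        {"chr": ann["chr"], "pos": ann["pos"], "ratio": ratios}
    ).sort_values(["chr", "pos"])
    segments: list[Segment] = []

    def best_split(vals: np.ndarray) -> tuple[int | None, float]:
        n = vals.size
        if n < 2 * min_probes:
            return None, 1.0
        csum = np.cumsum(vals)
        csum2 = np.cumsum(vals**2)
        total, total2 = csum[-1], csum2[-1]
        i = np.arange(min_probes, n - min_probes + 1)
        n1, n2 = i.astype(float), (n - i).astype(float)
        s1, s2 = csum[i - 1], total - csum[i - 1]
        ss1 = csum2[i - 1] - s1**2 / n1
        ss2 = (total2 - csum2[i - 1]) - s2**2 / n2
        dfree = n - 2
        pooled = (ss1 + ss2) / dfree
        pooled = np.maximum(pooled, 1e-12)
        t = (s1 / n1 - s2 / n2) / np.sqrt(pooled * (1 / n1 + 1 / n2))
        j = int(np.argmax(np.abs(t)))
        p = 2.0 * stats.t.sf(abs(t[j]), dfree)
        return int(i[j]), float(p)

    def recurse(chrom: str, pos: np.ndarray, vals: np.ndarray) -> None:
        split, p = best_split(vals)
        if split is not None and p < alpha:
            recurse(chrom, pos[:split], vals[:split])
            recurse(chrom, pos[split:], vals[split:])
        else:
            segments.append(
                Segment(
                    chrom=chrom,
                    start=int(pos.min()),
                    end=int(pos.max()),
                    n_probes=int(vals.size),
                    seg_log2=float(vals.mean()),
                )
            )

    for chrom, grp in df.groupby("chr", sort=True):
        recurse(str(chrom), grp["pos"].to_numpy(), grp["ratio"].to_numpy(dtype=float))
    segments.sort(key=lambda s: (s.chrom, s.start))
    return segments


def call_cna(segments: list[Segment], threshold: float = 0.5) -> list[Segment]:
    """Classify segments as gain (seg >= threshold), loss (<= -threshold) or neutral."""
    if threshold <= 0:
        raise ValidationError("call threshold must be positive")
    for s in segments:
        if s.seg_log2 >= threshold:
            s.call = "gain"
        elif s.seg_log2 <= -threshold:
            s.call = "loss"
        else:
            s.call = "neutral"
    return segments


def cna_profile(
    meth: pd.DataFrame,
    unmeth: pd.DataFrame,
    annotation: ProbeAnnotation,
    query_samples: list[str],
    reference_samples: list[str],
    min_probes: int = 10,
    alpha: float = 0.01,
    threshold: float = 0.5,
) -> CNAProfile:
    """Median-query-vs-reference copy-number profile with segments and calls.

    The median combined intensity of the query samples is compared to the
    reference cohort (probe-wise median), segmented, and called at
    ``threshold`` (|log2| >= 0.5 by default).
    """
    total = combined_intensity(meth, unmeth)
    query = total.loc[query_samples].median(axis=0)
    ratios = log2_ratio(query, total.loc[reference_samples])
    segments = call_cna(
        segment_profile(ratios, annotation, min_probes=min_probes, alpha=alpha),
        threshold=threshold,
    )
    ann = annotation.for_probes(ratios.index)
    probes = pd.DataFrame(
        {"chr": ann["chr"], "pos": ann["pos"], "log2_ratio": ratios}
    ).sort_values(["chr", "pos"])
    return CNAProfile(probes=probes, segments=segments)
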