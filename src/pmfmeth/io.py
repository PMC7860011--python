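"""Readers and writers for the pipeline's delimited file formats.

Matrices (beta, intensities, detection p) are tab-delimited with a header row
of probe ids and a first column of sample ids. The manifest and sample sheet
are CSV. Internal coordinates are 1-based inclusive; BED exports are 0-based
half-open, SEG exports 1-based.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ISLAND_VOCABULARY,
    BetaMatrix,
    ProbeAnnotation,
    SampleSheet,
    ValidationError,
)
from .differential import DMRRecord

_ISLAND_NORMALIZE = {v.lower(): v for v in ISLAND_VOCABULARY}
_ISLAND_NORMALIZE.update({"opensea": "OpenSea", "open_sea": "OpenSea", "": "OpenSea"})


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a samples x probes TSV matrix (first column = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Read and validate a beta-value matrix; errors carry cell coordinates."""
    return BetaMatrix(read_matrix(path))


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_manifest(path: str | Path) -> ProbeAnnotation:
    """Read a probe manifest CSV, normalizing island-relation capitalization."""
    df = pd.read_csv(path, index_col=0, keep_default_na=False)
    df.index = df.index.astype(str)
    if "island_relation" in df.columns:
        raw = df["island_relation"].astype(str)
        normalized = raw.map(lambda v: _ISLAND_NORMALIZE.get(v.strip().lower(), v))
        changed = (normalized != raw) & raw.str.strip().ne("")
        if changed.any():
            warnings.warn(
                f"normalized island_relation capitalization for {int(changed.sum())} "
                f"probe(s), e.g. {raw[changed].iloc[0]!r} -> {normalized[changed].iloc[0]!r}",
                stacklevel=2,
            )
        df["island_relation"] = normalized
    if "pos" in df.columns:
        df["pos"] = df["pos"].astype(int)
    if "gene" in df.columns:
        df["gene"] = df["gene"].astype(str)
    return ProbeAnnotation(df)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return SampleSheet(df)


def write_dmp_table(dmps: pd.DataFrame, path: str | Path) -> None:
    dmps.to_csv(path, sep="\t", index=False)


def write_dmr_bed(records: list[DMRRecord], path: str | Path) -> None:
    """Write DMRs as BED (0-based half-open), converted from 1-based inclusive."""
    with open(path, "w") as fh:
        for i, r in enumerate(records):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tDMR{i + 1}\t{r.area:.6g}\n")


def write_dmr_table(records: list[DMRRecord], path: str | Path) -> None:
    rows = [
        {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "n_probes": len(r.probe_ids),
            "probe_ids": ";".join(r.probe_ids),
            "area": r.area,
            "p": r.p,
            "q": r.q,
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_probes", "probe_ids", "area", "p", "q"]
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets in GMT format: term <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
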