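"""Variant allele frequencies and the clonal-fraction statistic.

A variant's VAF is the alt-supporting read count divided by total reads at
its position. Variants with VAF at or above a threshold (default 0.25) are
counted as clonal; the clonal fraction summarizes how genetically
homogeneous a sample is (low intra-tumor heterogeneity ⇒ fraction near 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from immunosift.io import ValidationError, VariantTable

__all__ = ["ClonalitySummary", "compute_vaf", "clonal_fraction", "vaf_density_log2"]


@dataclass
class ClonalitySummary:
    n_variants: int
    n_clonal: int
    clonal_fraction: float
    threshold: float
    strict: bool
    vaf_values: np.ndarray


def compute_vaf(table: VariantTable) -> VariantTable:
    """Populate the vaf column as alt_reads / total_reads (exact division)."""
    df = table.df.copy()
    if (df["total_reads"] < 1).any():
        raise ValidationError("total_reads must be >= 1 to compute VAF")
    df["vaf"] = df["alt_reads"] / df["total_reads"]
    return VariantTable(df)


def clonal_fraction(
    table: VariantTable, threshold: float = 0.25, strict: bool = False
) -> ClonalitySummary:
    """Fraction of variants with VAF >= threshold (or > threshold if strict).

    The inclusive boundary is the default; the strict variant exists because
    display conventions sometimes use a strict inequality at the threshold.
    """
    if len(table) == 0:
        raise ValidationError("clonal_fraction requires a non-empty variant table")
    vaf = table.vaf
    n_clonal = int((vaf > threshold).sum() if strict else (vaf >= threshold).sum())
    return ClonalitySummary(
        n_variants=len(vaf),
        n_clonal=n_clonal,
        clonal_fraction=n_clonal / len(vaf),
        threshold=threshold,
        strict=strict,
        vaf_values=np.asarray(vaf, dtype=float),
    )


def vaf_density_log2(table: VariantTable, n_bins: int = 50) -> pd.DataFrame:
    """Histogram density of log2(VAF) for plotting; zero-VAF variants dropped."""
    vaf = table.vaf
    vaf = vaf[vaf > 0]
    log2v = np.log2(vaf)
    hist, edges = np.histogram(log2v, bins=n_bins, density=True)
    return pd.DataFrame(
        {"log2_vaf_mid": (edges[:-1] + edges[1:]) / 2.0, "density": hist}
    )
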