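"""Cell-level quality control and log-normalization.

QC keeps cells whose detected-gene count lies within mean ± k·SD of their
library and whose mitochondrial read fraction is at most ``mito_max``.
Normalization is the standard single-cell convention: counts scaled to a
fixed total per cell, then log1p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from immunosift.io import ExpressionDataset, NormalizedMatrix, ValidationError

__all__ = ["QCReport", "filter_cells", "lognormalize"]


@dataclass
class QCReport:
    """Per-library QC bookkeeping: counts in/out and the SD bounds used."""

    per_library: pd.DataFrame

    def to_tsv(self, path: str) -> None:
        self.per_library.to_csv(path, sep="\t", index=False, float_format="%.10g")


def filter_cells(
    ds: ExpressionDataset,
    mito_max: float = 0.10,
    sd_k: float = 2.0,
    per: str = "replicate_id",
    mito_first: bool = True,
) -> tuple[ExpressionDataset, QCReport]:
    """Apply the mitochondrial and ±k·SD detected-gene filters.

    The SD bounds are computed on detected-gene counts within each library
    (grouping key ``per``). By default the mitochondrial filter runs first
    and SD bounds are computed on mito-passing cells, which keeps dying
    cells from dragging the bounds; ``mito_first=False`` computes bounds on
    all cells. Libraries with fewer than 3 cells skip the SD rule with a
    warning.
    """
    meta = ds.cell_meta
    if per not in meta.columns:
        raise ValidationError(f"grouping column not in cell metadata: {per}")
    n = ds.n_cells
    if mito_max is not None:
        if "pct_mito" not in meta.columns:
            raise ValidationError("pct_mito required for the mitochondrial filter")
        mito_pass = meta["pct_mito"].to_numpy(dtype=float) <= mito_max
    else:
        mito_pass = np.ones(n, dtype=bool)

    ngenes = meta["n_genes_detected"].to_numpy(dtype=float)
    bound_base = mito_pass if mito_first else np.ones(n, dtype=bool)
    keep = mito_pass.copy()
    rows = []
    for lib, idx in meta.groupby(per, sort=True).indices.items():
        idx = np.asarray(idx)
        base = idx[bound_base[idx]]
        if len(base) < 3:
            warnings.warn(
                f"library {lib!r} has {len(base)} cells; SD filter skipped", stacklevel=2
            )
            lo, hi = -np.inf, np.inf
        else:
            m = ngenes[base].mean()
            sd = ngenes[base].std(ddof=1)
            lo, hi = m - sd_k * sd, m + sd_k * sd
        sd_pass = (ngenes[idx] >= lo) & (ngenes[idx] <= hi)
        keep[idx] &= sd_pass
        rows.append(
            {
                "library": lib,
                "n_cells": len(idx),
                "n_kept": int(keep[idx].sum()),
                "n_removed_mito": int((~mito_pass[idx]).sum()),
                "n_removed_sd": int((mito_pass[idx] & ~sd_pass).sum()),
                "sd_lower": lo,
                "sd_upper": hi,
            }
        )
    return ds.subset_cells(keep), QCReport(per_library=pd.DataFrame(rows))


def lognormalize(ds: ExpressionDataset, scale_total: float = 10_000.0) -> NormalizedMatrix:
    """value(c, g) = ln(1 + scale_total * count(c, g) / libsize(c)).

    Cells with zero library size map to all-zero rows with a warning.
    """
    counts = ds.counts.astype(float)
    lib = counts.sum(axis=1)
    zero = lib == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cells have zero counts; rows left at 0", stacklevel=2)
        lib = np.where(zero, 1.0, lib)
    values = np.log1p(scale_total * counts / lib[:, None])
    return NormalizedMatrix(
        values=values,
        gene_names=list(ds.gene_names),
        cell_ids=ds.cell_ids,
        scale_total=scale_total,
    )
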