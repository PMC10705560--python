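"""Readers, writers and validated in-memory containers for pipeline inputs.

On-disk conventions: counts travel as MatrixMarket coordinate-integer MTX
with TSV sidecars (``genes.tsv``: one gene per line; ``cells.tsv``: one row
per cell with the metadata columns); variant, guide and survival tables are
tab-separated UTF-8 with a header row and "." decimal. TSV round-trips are
bit-exact up to float formatting at 10 significant digits. Variants may
alternatively arrive as a VCF whose per-sample AD field carries ref/alt
depths.

Matrix orientation on disk defaults to genes x cells (the 10x convention)
and is normalized internally to cells x genes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ValidationError",
    "ExpressionDataset",
    "NormalizedMatrix",
    "VariantTable",
    "GuideCountTable",
    "SurvivalTable",
    "read_expression",
    "write_expression",
    "read_variants",
    "write_variants",
    "read_guides",
    "write_guides",
    "read_survival",
    "write_survival",
]

GUIDE_ROLES = ("targeting", "non_targeting", "depletion_control", "enrichment_control")
SAMPLE_CONDITIONS = ("input", "endpoint")

REQUIRED_CELL_COLUMNS = ("clone_id", "group", "timepoint", "replicate_id", "cell_type")

_FLOAT_FMT = "%.10g"


class ValidationError(ValueError):
    """Raised when an input file or in-memory table violates an invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass
class ExpressionDataset:
    """Cell x gene integer counts plus per-cell metadata.

    ``counts`` is a dense non-negative integer array of shape
    (n_cells, n_genes); ``cell_meta`` is indexed by cell_id and carries
    clone_id, group, timepoint (days), replicate_id, cell_type and
    optionally pct_mito (fraction in [0, 1]). ``n_genes_detected`` is
    derived from counts on construction.
    """

    counts: np.ndarray
    gene_names: list[str]
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        _require(self.counts.ndim == 2, "counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        _require((self.counts >= 0).all(), "counts must be non-negative")
        self.gene_names = [str(g) for g in self.gene_names]
        _require(
            len(self.gene_names) == self.counts.shape[1],
            f"gene sidecar has {len(self.gene_names)} names for a "
            f"{self.counts.shape[1]}-gene matrix (dimension mismatch: genes)",
        )
        _require(
            len(set(self.gene_names)) == len(self.gene_names),
            "duplicate gene names",
        )
        _require(
            len(self.cell_meta) == self.counts.shape[0],
            f"cell sidecar has {len(self.cell_meta)} rows for a "
            f"{self.counts.shape[0]}-cell matrix (dimension mismatch: cells)",
        )
        for col in REQUIRED_CELL_COLUMNS:
            _require(col in self.cell_meta.columns, f"missing required metadata column: {col}")
            _require(
                not self.cell_meta[col].isna().any(),
                f"metadata column {col} has missing values",
            )
        self.cell_meta = self.cell_meta.copy()
        self.cell_meta["timepoint"] = self.cell_meta["timepoint"].astype(int)
        _require((self.cell_meta["timepoint"] >= 0).all(), "timepoint must be >= 0 days")
        if "pct_mito" in self.cell_meta.columns:
            pm = self.cell_meta["pct_mito"].astype(float)
            ok = pm.isna() | ((pm >= 0) & (pm <= 1))
            _require(bool(ok.all()), "pct_mito must lie in [0, 1]")
            self.cell_meta["pct_mito"] = pm
        # group must be constant within a clone
        ngroup = self.cell_meta.groupby("clone_id")["group"].nunique()
        bad = ngroup[ngroup > 1]
        _require(bad.empty, f"group is not constant within clone_id: {list(bad.index)}")
        self.cell_meta["n_genes_detected"] = (self.counts > 0).sum(axis=1)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def cell_ids(self) -> list[str]:
        return [str(c) for c in self.cell_meta.index]

    def subset_cells(self, mask: np.ndarray) -> "ExpressionDataset":
        mask = np.asarray(mask)
        return ExpressionDataset(
            counts=self.counts[mask],
            gene_names=list(self.gene_names),
            cell_meta=self.cell_meta.loc[mask]
            if mask.dtype == bool
            else self.cell_meta.iloc[mask],
        )


@dataclass
class NormalizedMatrix:
    """log1p of counts scaled to a fixed total per cell (default 10,000)."""

    values: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    scale_total: float = 10_000.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _require(self.scale_total > 0, "scale_total must be positive")
        _require((self.values >= 0).all(), "normalized values must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)


@dataclass
class VariantTable:
    """Per-variant read support and derived variant allele frequency."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in ("variant_id", "alt_reads", "total_reads"):
            _require(col in df.columns, f"variants table missing column: {col}")
        df["alt_reads"] = df["alt_reads"].astype(int)
        df["total_reads"] = df["total_reads"].astype(int)
        _require((df["alt_reads"] >= 0).all(), "alt_reads must be >= 0")
        _require((df["total_reads"] >= 1).all(), "total_reads must be >= 1")
        bad = df[df["alt_reads"] > df["total_reads"]]
        _require(
            bad.empty,
            f"alt_reads > total_reads for variants: {list(bad['variant_id'].head())}",
        )
        df["vaf"] = df["alt_reads"] / df["total_reads"]
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def vaf(self) -> np.ndarray:
        return self.df["vaf"].to_numpy()


@dataclass
class GuideCountTable:
    """sgRNA library counts: guide -> gene map with roles, counts per sample.

    ``counts`` columns are sample ids; ``sample_meta`` assigns each sample a
    condition (input library vs post-selection endpoint) and a replicate id.
    """

    guides: pd.DataFrame  # guide_id, gene, role
    counts: pd.DataFrame  # index guide_id, columns sample_id
    sample_meta: pd.DataFrame  # sample_id, condition, replicate_id

    def __post_init__(self) -> None:
        g = self.guides.copy()
        for col in ("guide_id", "gene", "role"):
            _require(col in g.columns, f"guides table missing column: {col}")
        _require(g["guide_id"].is_unique, "duplicate guide_id in guides table")
        bad_roles = sorted(set(g["role"]) - set(GUIDE_ROLES))
        _require(not bad_roles, f"unknown guide role(s): {bad_roles}")
        multi = g.groupby("guide_id")["gene"].nunique()
        _require((multi == 1).all(), "a guide maps to more than one gene")
        sm = self.sample_meta.copy()
        for col in ("sample_id", "condition", "replicate_id"):
            _require(col in sm.columns, f"sample_meta missing column: {col}")
        bad_cond = sorted(set(sm["condition"]) - set(SAMPLE_CONDITIONS))
        _require(not bad_cond, f"unknown sample condition(s): {bad_cond}")
        _require(
            (sm["condition"] == "input").any() and (sm["condition"] == "endpoint").any(),
            "need at least one input and one endpoint sample",
        )
        c = self.counts.copy()
        _require(
            list(c.index) == list(g["guide_id"]),
            "counts index must match guides table order",
        )
        _require(
            set(c.columns) == set(sm["sample_id"]),
            "counts columns must match sample_meta sample_ids",
        )
        arr = c.to_numpy()
        _require(
            np.issubdtype(arr.dtype, np.integer) or np.all(np.mod(arr, 1) == 0),
            "guide counts must be integers",
        )
        _require((arr >= 0).all(), "guide counts must be >= 0")
        self.guides = g.reset_index(drop=True)
        self.counts = c.astype(np.int64)
        self.sample_meta = sm.reset_index(drop=True)

    @property
    def guide_ids(self) -> list[str]:
        return list(self.guides["guide_id"])

    def samples(self, condition: str) -> list[str]:
        sm = self.sample_meta
        return list(sm.loc[sm["condition"] == condition, "sample_id"])


@dataclass
class SurvivalTable:
    """Per-subject follow-up time, event indicator and a numeric covariate."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in ("subject_id", "time", "event"):
            _require(col in df.columns, f"survival table missing column: {col}")
        df["time"] = df["time"].astype(float)
        _require((df["time"] > 0).all(), "survival times must be > 0")
        ev = df["event"].astype(int)
        _require(set(ev.unique()) <= {0, 1}, "event must be 0/1")
        df["event"] = ev
        if "covariate" in df.columns:
            df["covariate"] = df["covariate"].astype(float)
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# expression I/O


def read_expression(
    matrix_path: str,
    genes_path: str,
    cellmeta_path: str,
    orientation: str = "genes_by_cells",
) -> ExpressionDataset:
    """Read an MTX count matrix with genes.tsv / cells.tsv sidecars.

    ``orientation`` declares how the matrix is stored on disk
    ("genes_by_cells", the 10x convention, or "cells_by_genes"); the result
    is always cells x genes.
    """
    if orientation not in ("genes_by_cells", "cells_by_genes"):
        raise ValidationError(f"unknown orientation: {orientation}")
    mat = scipy.io.mmread(matrix_path)
    mat = scipy.sparse.coo_matrix(mat).toarray()
    if orientation == "genes_by_cells":
        mat = mat.T
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    meta = pd.read_csv(cellmeta_path, sep="\t", dtype={"cell_id": str})
    _require("cell_id" in meta.columns, f"missing required metadata column: cell_id in {cellmeta_path}")
    meta = meta.set_index("cell_id")
    try:
        return ExpressionDataset(counts=mat, gene_names=genes, cell_meta=meta)
    except ValidationError as exc:
        raise ValidationError(f"{exc} (while reading {matrix_path})") from exc


def write_expression(ds: ExpressionDataset, outdir: str, orientation: str = "genes_by_cells") -> dict:
    """Write matrix.mtx + genes.tsv + cells.tsv into ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "matrix": os.path.join(outdir, "matrix.mtx"),
        "genes": os.path.join(outdir, "genes.tsv"),
        "cells": os.path.join(outdir, "cells.tsv"),
    }
    mat = ds.counts.T if orientation == "genes_by_cells" else ds.counts
    scipy.io.mmwrite(paths["matrix"], scipy.sparse.coo_matrix(mat), field="integer")
    with open(paths["genes"], "w") as fh:
        fh.write("\n".join(ds.gene_names) + "\n")
    meta = ds.cell_meta.drop(columns=["n_genes_detected"], errors="ignore")
    meta.to_csv(paths["cells"], sep="\t", index_label="cell_id", float_format=_FLOAT_FMT)
    return paths


# ---------------------------------------------------------------------------
# variant I/O


def read_variants(path: str, sample: str | None = None) -> VariantTable:
    """Read a variants TSV (variant_id, alt_reads, total_reads) or a VCF.

    For VCF input the per-sample AD field (ref,alt depths) of ``sample``
    (default: first sample) is consumed; only CHROM/POS/ID identify the
    variant.
    """
    if path.endswith((".vcf", ".vcf.gz")):
        return _read_variants_vcf(path, sample)
    df = pd.read_csv(path, sep="\t")
    return VariantTable(df)


def _read_variants_vcf(path: str, sample: str | None) -> VariantTable:
    from cyvcf2 import VCF

    vcf = VCF(path)
    names = vcf.samples
    _require(bool(names), "VCF has no sample columns (AD needed)")
    idx = 0 if sample is None else names.index(sample)
    rows = []
    for rec in vcf:
        ad = rec.format("AD")
        _require(ad is not None, f"VCF record without AD at {rec.CHROM}:{rec.POS}")
        ref_d, alt_d = int(ad[idx][0]), int(ad[idx][1])
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        rows.append({"variant_id": vid, "alt_reads": alt_d, "total_reads": ref_d + alt_d})
    return VariantTable(pd.DataFrame(rows))


def write_variants(table: VariantTable, path: str) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# guide I/O

_GUIDE_FIXED = ["guide_id", "gene", "role"]


def read_guides(path: str, sample_meta_path: str | None = None) -> GuideCountTable:
    """Read a guides TSV: guide_id, gene, role, then one count column per sample.

    Sample metadata comes from ``sample_meta_path`` (TSV: sample_id,
    condition, replicate_id) or, if omitted, from ``<path>`` with suffix
    ``.samples.tsv``; failing that, sample names starting with "input" are
    treated as input libraries and the rest as endpoints.
    """
    df = pd.read_csv(path, sep="\t")
    for col in _GUIDE_FIXED:
        _require(col in df.columns, f"guides file {path} missing column: {col}")
    sample_cols = [c for c in df.columns if c not in _GUIDE_FIXED]
    _require(bool(sample_cols), "guides file has no count columns")
    if sample_meta_path is None:
        cand = path + ".samples.tsv"
        sample_meta_path = cand if os.path.exists(cand) else None
    if sample_meta_path is not None:
        sm = pd.read_csv(sample_meta_path, sep="\t")
    else:
        sm = pd.DataFrame(
            {
                "sample_id": sample_cols,
                "condition": ["input" if s.startswith("input") else "endpoint" for s in sample_cols],
                "replicate_id": sample_cols,
            }
        )
    counts = df[sample_cols].copy()
    counts.index = df["guide_id"]
    return GuideCountTable(guides=df[_GUIDE_FIXED], counts=counts, sample_meta=sm)


def write_guides(gc: GuideCountTable, path: str) -> None:
    out = pd.concat(
        [gc.guides.reset_index(drop=True), gc.counts.reset_index(drop=True)], axis=1
    )
    out.to_csv(path, sep="\t", index=False)
    gc.sample_meta.to_csv(path + ".samples.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# survival I/O


def read_survival(path: str) -> SurvivalTable:
    return SurvivalTable(pd.read_csv(path, sep="\t"))


def write_survival(table: SurvivalTable, path: str) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
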