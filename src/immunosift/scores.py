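"""Per-cell gene-set module scores and the bulk cytolytic-activity score.

A module score contrasts a gene set against expression-matched background:
genes are binned by average expression, control genes are drawn from each
member's bin, and a cell's score is its mean expression over the set minus
its mean over the pooled controls. Zero means "no different from matched
background"; the score is invariant to adding a constant to every gene.

Cytolytic activity (CYT) of a bulk sample is the geometric mean of
(GZMA + 1) and (PRF1 + 1) expression, computed via the exp/ln form
exp((ln(GZMA+1) + ln(PRF1+1)) / 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from immunosift.io import NormalizedMatrix, ValidationError

__all__ = [
    "ModuleScoreResult",
    "module_score",
    "exhaustion_score",
    "cytolytic_activity",
    "replicate_score_comparison",
]


@dataclass
class ModuleScoreResult:
    scores: np.ndarray  # one per cell
    cell_ids: list[str]
    gene_set: list[str]  # members found in the matrix
    control_genes: list[str]
    n_bins: int
    n_ctrl_per_bin: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids, "score": self.scores})


def module_score(
    norm: NormalizedMatrix,
    gene_set: list[str],
    n_bins: int = 25,
    n_ctrl_per_bin: int = 100,
    seed: int = 0,
) -> ModuleScoreResult:
    """Expression-bin-matched module score for every cell in ``norm``.

    Genes are ranked by mean expression across cells and cut into
    ``n_bins`` equal-frequency bins (ties broken by stable gene order).
    For each gene-set member, up to ``n_ctrl_per_bin`` control genes are
    sampled without replacement from its bin, excluding gene-set members;
    the pooled (deduplicated) controls give the background mean.
    """
    present = [g for g in gene_set if g in set(norm.gene_names)]
    missing = sorted(set(gene_set) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} gene-set genes absent from matrix", stacklevel=2)
    if not present:
        raise ValidationError("gene set has empty intersection with the matrix genes")

    rng = np.random.default_rng(seed)
    means = norm.values.mean(axis=0)
    order = np.argsort(means, kind="stable")
    bin_of = np.empty(len(means), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b

    name_to_idx = {g: i for i, g in enumerate(norm.gene_names)}
    set_idx = np.array([name_to_idx[g] for g in present])
    set_mask = np.zeros(len(means), dtype=bool)
    set_mask[set_idx] = True

    ctrl: set[int] = set()
    for gi in set_idx:
        candidates = np.flatnonzero((bin_of == bin_of[gi]) & ~set_mask)
        take = min(n_ctrl_per_bin, len(candidates))
        if take < n_ctrl_per_bin:
            warnings.warn(
                f"bin {bin_of[gi]} has only {len(candidates)} control candidates "
                f"(< {n_ctrl_per_bin}); sampling all",
                stacklevel=2,
            )
        ctrl.update(rng.choice(candidates, size=take, replace=False).tolist())
    ctrl_idx = np.array(sorted(ctrl), dtype=int)
    if ctrl_idx.size == 0:
        raise ValidationError("no control genes available outside the gene set")

    scores = norm.values[:, set_idx].mean(axis=1) - norm.values[:, ctrl_idx].mean(axis=1)
    return ModuleScoreResult(
        scores=scores,
        cell_ids=list(norm.cell_ids),
        gene_set=present,
        control_genes=[norm.gene_names[i] for i in ctrl_idx],
        n_bins=n_bins,
        n_ctrl_per_bin=n_ctrl_per_bin,
        seed=seed,
    )


def exhaustion_score(
    norm: NormalizedMatrix,
    meta: pd.DataFrame,
    exhaustion_genes: list[str],
    cell_types: tuple[str, ...] = ("T_CD8",),
    n_bins: int = 25,
    n_ctrl_per_bin: int = 100,
    seed: int = 0,
) -> ModuleScoreResult:
    """Module score of a T-cell dysfunction signature on CD8 T cells.

    Identical algorithm to :func:`module_score`, run on the cells whose
    ``cell_type`` is in ``cell_types`` (expression bins are recomputed on
    those cells so the background matches the scored population).
    """
    if len(meta) != norm.shape[0]:
        raise ValidationError("metadata rows do not match normalized matrix cells")
    mask = meta["cell_type"].isin(cell_types).to_numpy()
    if not mask.any():
        raise ValidationError(f"no cells of types {cell_types}")
    sub = NormalizedMatrix(
        values=norm.values[mask],
        gene_names=list(norm.gene_names),
        cell_ids=[c for c, m in zip(norm.cell_ids, mask) if m],
        scale_total=norm.scale_total,
    )
    return module_score(sub, exhaustion_genes, n_bins=n_bins, n_ctrl_per_bin=n_ctrl_per_bin, seed=seed)


def replicate_score_comparison(
    result: ModuleScoreResult,
    meta: pd.DataFrame,
    groups: tuple[str, str] | None = None,
    timepoint: int | None = None,
    unit: str = "replicate",
) -> dict:
    """Two-sided Wilcoxon comparison of scores between groups.

    The test unit is the biological replicate by default (each point is a
    replicate's mean score); ``unit="cell"`` tests single cells instead.
    """
    df = pd.DataFrame({"score": result.scores}, index=pd.Index(result.cell_ids, name="cell_id"))
    df = df.join(meta[["group", "replicate_id", "timepoint"]], how="left")
    if timepoint is not None:
        df = df[df["timepoint"] == timepoint]
    if groups is None:
        present = sorted(df["group"].dropna().unique())
        if len(present) != 2:
            raise ValidationError(f"need exactly 2 groups, got {present}")
        groups = (present[0], present[1])
    if unit == "replicate":
        per = df.groupby(["group", "replicate_id"])["score"].mean().reset_index()
        a = per.loc[per["group"] == groups[0], "score"].to_numpy()
        b = per.loc[per["group"] == groups[1], "score"].to_numpy()
    elif unit == "cell":
        a = df.loc[df["group"] == groups[0], "score"].to_numpy()
        b = df.loc[df["group"] == groups[1], "score"].to_numpy()
    else:
        raise ValidationError(f"unknown unit: {unit}")
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need >= 2 observations per group")
    combined = np.r_[a, b]
    if np.all(combined == combined[0]):
        p_value = 1.0
    else:
        method = (
            "exact"
            if max(len(a), len(b)) <= 25 and len(np.unique(combined)) == len(combined)
            else "asymptotic"
        )
        p_value = float(scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
    return {
        "groups": groups,
        "p_value": p_value,
        "mean_a": float(np.mean(a)),
        "mean_b": float(np.mean(b)),
        "n_a": len(a),
        "n_b": len(b),
        "unit": unit,
    }


def cytolytic_activity(gzma, prf1) -> np.ndarray:
    """CYT = exp((ln(GZMA+1) + ln(PRF1+1)) / 2) per sample; always >= 1."""
    gzma = np.asarray(gzma, dtype=float)
    prf1 = np.asarray(prf1, dtype=float)
    if (gzma < 0).any() or (prf1 < 0).any():
        raise ValidationError("expression inputs to CYT must be >= 0")
    return np.exp((np.log1p(gzma) + np.log1p(prf1)) / 2.0)
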