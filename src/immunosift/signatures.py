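"""Per-timepoint differential expression, core signatures, and recurrence.

The comparison of interest is tumor cells of rejected versus non-rejected
clones at each day post-inoculation, tested gene-by-gene with the
two-sided Wilcoxon rank-sum test on log-normalized expression. A gene is
significant when its fold change exceeds ``fc_threshold`` and its
Bonferroni-corrected p-value is below ``alpha``. The core signature of a
group at a timepoint is the subset of significant genes whose scaled
per-clone mean expression (z across all clones) exceeds ``z_threshold`` in
every clone of that group and is negative in every clone of the other —
i.e. genes consistently shifted in *all* clones, not driven by one.
Recurrent genes are those significantly up in the same group at two or
more timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from immunosift.io import NormalizedMatrix, ValidationError

__all__ = [
    "DETable",
    "CoreSignature",
    "RecurrenceResult",
    "differential_expression",
    "core_signature",
    "recurrent_genes",
]


@dataclass
class DETable:
    """Differential-expression results for one timepoint.

    ``table`` is indexed by gene with columns mean_norm_A/B (means of
    expm1(normalized value)), avg_log2FC (A vs B), p_value,
    p_adj_bonferroni, direction (up_in_A / up_in_B / ns), n_cells_A/B,
    pct_expr_A/B. ``groups`` records which label is A and which is B.
    """

    table: pd.DataFrame
    timepoint: int
    groups: tuple[str, str]
    n_tested: int
    fc_threshold: float
    alpha: float

    def significant(self, direction: str | None = None) -> list[str]:
        t = self.table
        if direction is None:
            mask = t["direction"] != "ns"
        else:
            mask = t["direction"] == direction
        return list(t.index[mask])

    def up_in(self, group: str) -> list[str]:
        if group == self.groups[0]:
            return self.significant("up_in_A")
        if group == self.groups[1]:
            return self.significant("up_in_B")
        raise ValidationError(f"unknown group {group!r}; this table compares {self.groups}")


@dataclass
class CoreSignature:
    """Group-consistent genes at one timepoint plus the z matrix behind them."""

    timepoint: int
    groups: tuple[str, str]
    core_a_genes: list[str]
    core_b_genes: list[str]
    z_matrix: pd.DataFrame  # genes x clones
    clone_groups: dict[str, str]
    z_threshold: float
    excluded_zero_sd: list[str] = field(default_factory=list)

    def core(self, group: str) -> list[str]:
        if group == self.groups[0]:
            return self.core_a_genes
        if group == self.groups[1]:
            return self.core_b_genes
        raise ValidationError(f"unknown group {group!r}")


@dataclass
class RecurrenceResult:
    group: str
    min_timepoints: int
    gene_timepoints: dict[str, list[int]]
    recurrent: list[str]


def _wilcoxon_pvalues(X: np.ndarray, Y: np.ndarray, exact_max_n: int = 25) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per column.

    Exact enumeration when both groups have at most ``exact_max_n``
    observations and the column has no ties; otherwise the tie-corrected,
    continuity-corrected normal approximation.
    """
    nA, nB = X.shape[0], Y.shape[0]
    if nA <= exact_max_n and nB <= exact_max_n:
        out = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            x, y = X[:, j], Y[:, j]
            combined = np.concatenate([x, y])
            method = "exact" if len(np.unique(combined)) == len(combined) else "asymptotic"
            out[j] = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
        return out
    return scipy.stats.mannwhitneyu(X, Y, alternative="two-sided", method="asymptotic", axis=0).pvalue


def differential_expression(
    norm: NormalizedMatrix,
    meta: pd.DataFrame,
    timepoint: int,
    cell_type: str | None = "tumor",
    groups: tuple[str, str] | None = None,
    fc_threshold: float = 1.5,
    alpha: float = 0.01,
    min_pct: float = 0.10,
) -> DETable:
    """Wilcoxon rank-sum DE between the two groups at one timepoint.

    Only genes detected in at least ``min_pct`` of cells in at least one
    group are tested; Bonferroni correction is over the tested genes.
    avg_log2FC = log2((mean(expm1 A)+1) / (mean(expm1 B)+1)).
    """
    if len(meta) != norm.shape[0]:
        raise ValidationError("metadata rows do not match normalized matrix cells")
    sel = meta["timepoint"].to_numpy() == timepoint
    if not sel.any():
        raise ValidationError(f"timepoint {timepoint} absent from metadata")
    if cell_type is not None:
        sel &= meta["cell_type"].to_numpy() == cell_type
    sub = meta.loc[sel]
    if groups is None:
        present = sorted(sub["group"].unique())
        if len(present) != 2:
            raise ValidationError(f"need exactly 2 groups at timepoint {timepoint}, got {present}")
        groups = (present[0], present[1])
    ga, gb = groups
    mask_a = sel & (meta["group"].to_numpy() == ga)
    mask_b = sel & (meta["group"].to_numpy() == gb)
    for g, m in ((ga, mask_a), (gb, mask_b)):
        if m.sum() < 2:
            raise ValidationError(f"group {g!r} has {int(m.sum())} cells at timepoint {timepoint}")

    X = norm.values[mask_a]
    Y = norm.values[mask_b]
    pct_a = (X > 0).mean(axis=0)
    pct_b = (Y > 0).mean(axis=0)
    tested = (pct_a >= min_pct) | (pct_b >= min_pct)
    m_tested = int(tested.sum())
    if m_tested == 0:
        raise ValidationError("no genes pass the detection filter")

    pvals = _wilcoxon_pvalues(X[:, tested], Y[:, tested])
    mean_a = np.expm1(X[:, tested]).mean(axis=0)
    mean_b = np.expm1(Y[:, tested]).mean(axis=0)
    lfc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    p_adj = np.minimum(1.0, pvals * m_tested)
    log_fc_thr = np.log2(fc_threshold)
    direction = np.where(
        (p_adj < alpha) & (lfc > log_fc_thr),
        "up_in_A",
        np.where((p_adj < alpha) & (lfc < -log_fc_thr), "up_in_B", "ns"),
    )
    genes = np.asarray(norm.gene_names)[tested]
    table = pd.DataFrame(
        {
            "mean_norm_A": mean_a,
            "mean_norm_B": mean_b,
            "avg_log2FC": lfc,
            "p_value": pvals,
            "p_adj_bonferroni": p_adj,
            "direction": direction,
            "n_cells_A": X.shape[0],
            "n_cells_B": Y.shape[0],
            "pct_expr_A": pct_a[tested],
            "pct_expr_B": pct_b[tested],
        },
        index=pd.Index(genes, name="gene"),
    )
    return DETable(
        table=table,
        timepoint=timepoint,
        groups=groups,
        n_tested=m_tested,
        fc_threshold=fc_threshold,
        alpha=alpha,
    )


def core_signature(
    de: DETable,
    norm: NormalizedMatrix,
    meta: pd.DataFrame,
    z_threshold: float = 0.1,
    cell_type: str | None = "tumor",
) -> CoreSignature:
    """Consistency filter over the significant genes of one timepoint.

    The significant genes' normalized expression is averaged per clone
    (tumor cells at the table's timepoint), scaled to z-scores across all
    clones jointly (SD with denominator n−1), and a gene joins a group's
    core set iff z > ``z_threshold`` in every clone of that group and z < 0
    in every clone of the other. Requires at least 2 clones per group —
    with a single clone, "consistent in all clones" is vacuous and the
    statistic is not meaningful.
    """
    if len(meta) != norm.shape[0]:
        raise ValidationError("metadata rows do not match normalized matrix cells")
    sel = meta["timepoint"].to_numpy() == de.timepoint
    if cell_type is not None:
        sel &= meta["cell_type"].to_numpy() == cell_type
    sub = meta.loc[sel]
    ga, gb = de.groups
    clone_groups = sub.groupby("clone_id")["group"].first().to_dict()
    clones_a = sorted(c for c, g in clone_groups.items() if g == ga)
    clones_b = sorted(c for c, g in clone_groups.items() if g == gb)
    if len(clones_a) < 2 or len(clones_b) < 2:
        raise ValidationError(
            f"core signature needs >= 2 clones per group at timepoint {de.timepoint} "
            f"(got {len(clones_a)} {ga!r}, {len(clones_b)} {gb!r}); with one clone the "
            "all-clone consistency rule is vacuous"
        )
    sig_genes = de.significant()
    clones = clones_a + clones_b
    if not sig_genes:
        empty = pd.DataFrame(index=pd.Index([], name="gene"), columns=clones, dtype=float)
        return CoreSignature(de.timepoint, de.groups, [], [], empty, clone_groups, z_threshold)

    gidx = norm.gene_index(sig_genes)
    clone_means = np.empty((len(sig_genes), len(clones)))
    clone_ids = meta["clone_id"].to_numpy()
    for k, clone in enumerate(clones):
        cmask = sel & (clone_ids == clone)
        clone_means[:, k] = norm.values[np.ix_(cmask, gidx)].mean(axis=0)
    mu = clone_means.mean(axis=1, keepdims=True)
    sd = clone_means.std(axis=1, ddof=1, keepdims=True)
    zero_sd = sd[:, 0] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (clone_means - mu) / sd
    z_matrix = pd.DataFrame(z, index=pd.Index(sig_genes, name="gene"), columns=clones)

    ia = [clones.index(c) for c in clones_a]
    ib = [clones.index(c) for c in clones_b]
    ok = ~zero_sd
    core_a = ok & (z[:, ia] > z_threshold).all(axis=1) & (z[:, ib] < 0).all(axis=1)
    core_b = ok & (z[:, ib] > z_threshold).all(axis=1) & (z[:, ia] < 0).all(axis=1)
    return CoreSignature(
        timepoint=de.timepoint,
        groups=de.groups,
        core_a_genes=sorted(np.asarray(sig_genes)[core_a]),
        core_b_genes=sorted(np.asarray(sig_genes)[core_b]),
        z_matrix=z_matrix,
        clone_groups=clone_groups,
        z_threshold=z_threshold,
        excluded_zero_sd=sorted(np.asarray(sig_genes)[zero_sd]),
    )


def recurrent_genes(
    de_tables: Sequence[DETable],
    group: str,
    min_timepoints: int = 2,
) -> RecurrenceResult:
    """Genes significantly up in ``group`` at >= ``min_timepoints`` timepoints."""
    if len(de_tables) < max(2, min_timepoints):
        raise ValidationError(
            f"need at least {max(2, min_timepoints)} DE tables, got {len(de_tables)}"
        )
    gene_tps: dict[str, list[int]] = {}
    for de in de_tables:
        for gene in de.up_in(group):
            gene_tps.setdefault(gene, []).append(de.timepoint)
    recurrent = sorted(g for g, tps in gene_tps.items() if len(tps) >= min_timepoints)
    return RecurrenceResult(
        group=group,
        min_timepoints=min_timepoints,
        gene_timepoints={g: sorted(t) for g, t in sorted(gene_tps.items())},
        recurrent=recurrent,
    )
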