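"""Cell-type composition per replicate and group comparison.

Proportions are exact count ratios within a replicate x timepoint over a
chosen denominator compartment (all cells, immune, myeloid, or T cells).
Groups are compared with a two-sided Wilcoxon rank-sum test on
replicate-level fractions — the biological replicate (mouse/tumor), not
the cell, is the test unit, matching how composition boxplots are drawn.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from immunosift.io import ExpressionDataset, ValidationError

__all__ = ["DENOMINATORS", "cell_type_proportions", "compare_proportions"]

MYELOID = ("macrophage", "monocyte", "DC")
T_CELLS = ("T_CD8", "T_CD4", "Treg")

DENOMINATORS = ("all_cells", "immune", "myeloid", "t_cells")


def _denominator_mask(cell_type: pd.Series, denominator: str) -> pd.Series:
    if denominator == "all_cells":
        return pd.Series(True, index=cell_type.index)
    if denominator == "immune":
        return cell_type != "tumor"
    if denominator == "myeloid":
        return cell_type.isin(MYELOID)
    if denominator == "t_cells":
        return cell_type.isin(T_CELLS)
    raise ValidationError(f"unknown denominator: {denominator} (expected one of {DENOMINATORS})")


def cell_type_proportions(
    ds: ExpressionDataset | pd.DataFrame, denominator: str = "all_cells"
) -> pd.DataFrame:
    """Per-replicate cell-type fractions within the denominator compartment.

    Returns rows of (replicate_id, clone_id, group, timepoint, cell_type,
    n_cells, fraction, denominator). Replicates with no cells in the
    denominator are dropped with a warning. Fractions sum to 1 within each
    replicate x timepoint.
    """
    meta = ds.cell_meta if isinstance(ds, ExpressionDataset) else ds
    mask = _denominator_mask(meta["cell_type"], denominator)
    n_empty = meta.loc[~mask.groupby(meta["replicate_id"]).transform("any"), "replicate_id"].nunique()
    if n_empty:
        warnings.warn(
            f"{n_empty} replicate(s) have no cells in denominator {denominator!r}; dropped",
            stacklevel=2,
        )
    sub = meta.loc[mask]
    if sub.empty:
        raise ValidationError(f"no cells in denominator {denominator!r}")
    keys = ["replicate_id", "clone_id", "group", "timepoint"]
    counts = sub.groupby(keys + ["cell_type"], sort=True).size().rename("n_cells").reset_index()
    totals = counts.groupby("replicate_id")["n_cells"].transform("sum")
    counts["fraction"] = counts["n_cells"] / totals
    counts["denominator"] = denominator
    return counts


def compare_proportions(
    pt: pd.DataFrame,
    cell_type: str,
    timepoint: int,
    groups: tuple[str, str] | None = None,
) -> dict:
    """Two-sided Wilcoxon rank-sum on replicate-level fractions.

    Exact when both groups have at most 25 replicates and no ties; the
    tie-corrected normal approximation otherwise. Replicates present in the
    table but with zero cells of ``cell_type`` contribute fraction 0.
    """
    sub = pt[pt["timepoint"] == timepoint]
    if sub.empty:
        raise ValidationError(f"timepoint {timepoint} absent from proportion table")
    if groups is None:
        present = sorted(sub["group"].unique())
        if len(present) != 2:
            raise ValidationError(f"need exactly 2 groups, got {present}")
        groups = (present[0], present[1])
    # every replicate contributes; missing cell_type rows count as 0
    reps = sub[["replicate_id", "group"]].drop_duplicates().set_index("replicate_id")
    frac = (
        sub[sub["cell_type"] == cell_type]
        .set_index("replicate_id")["fraction"]
        .reindex(reps.index)
        .fillna(0.0)
    )
    a = frac[reps["group"] == groups[0]].to_numpy()
    b = frac[reps["group"] == groups[1]].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValidationError(
            f"need >= 2 replicates per group at timepoint {timepoint} "
            f"(got {len(a)} {groups[0]!r}, {len(b)} {groups[1]!r})"
        )
    combined = np.r_[a, b]
    if np.all(combined == combined[0]):
        # complete ties: the rank distribution is degenerate, p = 1 exactly
        p_value = 1.0
    else:
        exact = len(a) <= 25 and len(b) <= 25 and len(np.unique(combined)) == len(combined)
        p_value = float(
            scipy.stats.mannwhitneyu(
                a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
            ).pvalue
        )
    return {
        "cell_type": cell_type,
        "timepoint": timepoint,
        "groups": groups,
        "p_value": p_value,
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "n_per_group": (len(a), len(b)),
    }
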