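from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import immunosift as ims
from immunosift.io import ValidationError


def _meta(rows):
    df = pd.DataFrame(rows, columns=["replicate_id", "clone_id", "group", "timepoint", "cell_type"])
    df.index = pd.Index([f"c{i}" for i in range(len(df))], name="cell_id")
    return df


def test_proportions_exact_ratios_and_denominators():
    rows = (
        [("r1", "k1", "A", 0, "macrophage")] * 10
        + [("r1", "k1", "A", 0, "T_CD8")] * 90
        + [("r1", "k1", "A", 0, "tumor")] * 100
    )
    pt = ims.cell_type_proportions(_meta(rows), denominator="immune")
    mac = pt.query("cell_type == 'macrophage'")["fraction"].iloc[0]
    assert mac == pytest.approx(0.10)  # 10 macrophages among 100 immune cells
    # tumor cells excluded from numerator and denominator
    assert "tumor" not in set(pt["cell_type"])
    pt_all = ims.cell_type_proportions(_meta(rows), denominator="all_cells")
    assert pt_all.query("cell_type == 'macrophage'")["fraction"].iloc[0] == pytest.approx(0.05)
    with pytest.raises(ValidationError, match="denominator"):
        ims.cell_type_proportions(_meta(rows), denominator="everything")


def test_proportions_sum_to_one(small_experiment):
    ds, _ = small_experiment
    for denom in ("all_cells", "immune", "myeloid", "t_cells"):
        pt = ims.cell_type_proportions(ds, denominator=denom)
        sums = pt.groupby(["replicate_id", "timepoint"])["fraction"].sum()
        np.testing.assert_allclose(sums, 1.0, rtol=1e-12)


def _prop_table(fracs_a, fracs_b, cell_type="macrophage"):
    rows = []
    for i, f in enumerate(fracs_a):
        rows.append({"replicate_id": f"a{i}", "clone_id": f"a{i}", "group": "A", "timepoint": 0, "cell_type": cell_type, "fraction": f, "n_cells": 1, "denominator": "immune"})
    for i, f in enumerate(fracs_b):
        rows.append({"replicate_id": f"b{i}", "clone_id": f"b{i}", "group": "B", "timepoint": 0, "cell_type": cell_type, "fraction": f, "n_cells": 1, "denominator": "immune"})
    return pd.DataFrame(rows)


def brute_force_ranksum_p(x, y):
    combined = np.concatenate([x, y])
    ranks = combined.argsort().argsort() + 1.0
    n1, n = len(x), len(combined)
    center = n1 * (n - n1) / 2
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    hits = total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            hits += 1
    return hits / total


def test_compare_proportions_exact_and_ties():
    pt = _prop_table([0.31, 0.12, 0.27], [0.05, 0.02, 0.09])
    res = ims.compare_proportions(pt, "macrophage", 0, groups=("A", "B"))
    assert res["p_value"] == pytest.approx(
        brute_force_ranksum_p([0.31, 0.12, 0.27], [0.05, 0.02, 0.09]), abs=1e-12
    )
    # identical fraction vectors: complete ties, p = 1
    tied = _prop_table([0.1, 0.1, 0.1], [0.1, 0.1, 0.1])
    assert ims.compare_proportions(tied, "macrophage", 0, groups=("A", "B"))["p_value"] == 1.0
    # label swap leaves p unchanged
    swapped = ims.compare_proportions(pt, "macrophage", 0, groups=("B", "A"))
    assert swapped["p_value"] == res["p_value"]


def test_compare_proportions_requires_replicates():
    pt = _prop_table([0.3], [0.1, 0.2])
    with pytest.raises(ValidationError, match="replicates"):
        ims.compare_proportions(pt, "macrophage", 0, groups=("A", "B"))


def test_planted_macrophage_enrichment_power():
    """0.20 vs 0.05 expected fractions, 5 replicates per group, 200 cells
    per replicate: the Wilcoxon comparison should almost always detect it."""
    rng = np.random.default_rng(0)
    hits = 0
    n_runs = 100
    for _ in range(n_runs):
        fa = rng.binomial(200, 0.20, size=5) / 200
        fb = rng.binomial(200, 0.05, size=5) / 200
        pt = _prop_table(list(fa), list(fb))
        res = ims.compare_proportions(pt, "macrophage", 0, groups=("A", "B"))
        hits += res["p_value"] < 0.05
    assert hits / n_runs >= 0.90


def test_group_difference_recovered_from_generator(small_experiment):
    ds, truth = small_experiment
    pt = ims.cell_type_proportions(ds, denominator="all_cells")
    res = ims.compare_proportions(pt, "macrophage", 0, groups=("rejected", "non_rejected"))
    # macrophages planted at 0.12 in non-rejected vs 0.05 in rejected
    assert res["median_b"] > res["median_a"]
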