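from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import immunosift as ims
from immunosift.io import ValidationError
from immunosift.signatures import _wilcoxon_pvalues
from conftest import make_norm


def brute_force_wilcoxon_p(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    combined = np.concatenate([x, y])
    n, n1 = len(combined), len(x)
    ranks = combined.argsort().argsort() + 1.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    center = n1 * (n - n1) / 2
    count = total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return count / total


@pytest.mark.parametrize("sizes", [(4, 4), (5, 6), (3, 8)])
def test_exact_wilcoxon_matches_enumeration(sizes):
    rng = np.random.default_rng(1)
    for _ in range(5):
        x = rng.normal(size=sizes[0])
        y = rng.normal(size=sizes[1])
        p = _wilcoxon_pvalues(x[:, None], y[:, None])[0]
        assert p == pytest.approx(brute_force_wilcoxon_p(x, y), abs=1e-12)


def _two_group_norm():
    rng = np.random.default_rng(5)
    values = rng.gamma(1.0, 1.0, size=(40, 6))
    values[:20, 0] += 2.0  # gene g0 up in group A cells
    meta = pd.DataFrame(
        {
            "clone_id": ["a1"] * 10 + ["a2"] * 10 + ["b1"] * 10 + ["b2"] * 10,
            "group": ["A"] * 20 + ["B"] * 20,
            "timepoint": 0,
            "replicate_id": "r",
            "cell_type": "tumor",
        },
        index=pd.Index([f"c{i}" for i in range(40)], name="cell_id"),
    )
    return make_norm(values, cells=list(meta.index)), meta


def test_de_label_swap_antisymmetry():
    norm, meta = _two_group_norm()
    de_ab = ims.differential_expression(norm, meta, 0, groups=("A", "B"))
    de_ba = ims.differential_expression(norm, meta, 0, groups=("B", "A"))
    common = de_ab.table.index
    np.testing.assert_allclose(
        de_ab.table["avg_log2FC"], -de_ba.table.loc[common, "avg_log2FC"], rtol=1e-12
    )
    np.testing.assert_allclose(
        de_ab.table["p_value"], de_ba.table.loc[common, "p_value"], rtol=1e-12
    )


def test_de_identical_groups_and_bonferroni():
    values = np.tile(np.linspace(0, 2, 8)[:, None], (1, 5))
    meta = pd.DataFrame(
        {
            "clone_id": ["a"] * 4 + ["b"] * 4,
            "group": ["A"] * 4 + ["B"] * 4,
            "timepoint": 0,
            "replicate_id": "r",
            "cell_type": "tumor",
        },
        index=pd.Index([f"c{i}" for i in range(8)], name="cell_id"),
    )
    # group B cells see exactly the same value multiset as group A
    values[4:] = values[:4]
    de = ims.differential_expression(make_norm(values, cells=list(meta.index)), meta, 0)
    assert (de.table["avg_log2FC"] == 0).all()
    assert (de.table["direction"] == "ns").all()
    np.testing.assert_allclose(
        de.table["p_adj_bonferroni"], np.minimum(1.0, de.table["p_value"] * de.n_tested)
    )


def test_de_errors():
    norm, meta = _two_group_norm()
    with pytest.raises(ValidationError, match="timepoint"):
        ims.differential_expression(norm, meta, 99)
    solo = meta.copy()
    solo["group"] = "A"
    with pytest.raises(ValidationError):
        ims.differential_expression(norm, solo, 0, groups=("A", "B"))


def _de_marking(genes, significant):
    """Minimal DETable marking the given genes significant up in A."""
    table = pd.DataFrame(
        {
            "avg_log2FC": [2.0 if g in significant else 0.0 for g in genes],
            "p_value": 1e-6,
            "p_adj_bonferroni": [1e-4 if g in significant else 1.0 for g in genes],
            "direction": ["up_in_A" if g in significant else "ns" for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    return ims.DETable(table=table, timepoint=0, groups=("A", "B"), n_tested=len(genes), fc_threshold=1.5, alpha=0.01)


def test_core_signature_rule_matches_independent_z():
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(30)]
    clones = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "b3": "B"}
    # each clone contributes 4 cells with constant per-gene values => clone
    # means are exact and the z matrix can be recomputed independently
    clone_values = {c: rng.uniform(0.1, 3.0, size=len(genes)) for c in clones}
    values = np.vstack([np.tile(clone_values[c], (4, 1)) for c in clones])
    meta = pd.DataFrame(
        {
            "clone_id": np.repeat(list(clones), 4),
            "group": np.repeat([clones[c] for c in clones], 4),
            "timepoint": 0,
            "replicate_id": "r",
            "cell_type": "tumor",
        },
        index=pd.Index([f"c{i}" for i in range(20)], name="cell_id"),
    )
    norm = make_norm(values, genes=genes, cells=list(meta.index))
    de = _de_marking(genes, set(genes))  # all significant: test the z rule alone
    core = ims.core_signature(de, norm, meta, z_threshold=0.1)

    order = sorted(clones)
    M = np.array([clone_values[c] for c in order]).T  # genes x clones
    z = (M - M.mean(1, keepdims=True)) / M.std(1, ddof=1, keepdims=True)
    ia = [order.index(c) for c in order if clones[c] == "A"]
    ib = [order.index(c) for c in order if clones[c] == "B"]
    exp_a = {genes[i] for i in range(len(genes)) if (z[i, ia] > 0.1).all() and (z[i, ib] < 0).all()}
    exp_b = {genes[i] for i in range(len(genes)) if (z[i, ib] > 0.1).all() and (z[i, ia] < 0).all()}
    assert set(core.core_a_genes) == exp_a
    assert set(core.core_b_genes) == exp_b
    assert not set(core.core_a_genes) & set(core.core_b_genes)
    np.testing.assert_allclose(core.z_matrix[sorted(core.z_matrix.columns)].to_numpy(), z, rtol=1e-10)


def test_core_signature_zero_sd_excluded():
    genes = ["flat", "varying"]
    clones = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    rows = []
    for i, c in enumerate(sorted(clones)):
        rows.append([1.0, float(i)])
    values = np.repeat(np.array(rows), 3, axis=0)
    meta = pd.DataFrame(
        {
            "clone_id": np.repeat(sorted(clones), 3),
            "group": np.repeat([clones[c] for c in sorted(clones)], 3),
            "timepoint": 0,
            "replicate_id": "r",
            "cell_type": "tumor",
        },
        index=pd.Index([f"c{i}" for i in range(12)], name="cell_id"),
    )
    norm = make_norm(values, genes=genes, cells=list(meta.index))
    core = ims.core_signature(_de_marking(genes, set(genes)), norm, meta)
    assert core.excluded_zero_sd == ["flat"]
    assert "flat" not in core.core_a_genes + core.core_b_genes


def test_core_signature_refuses_single_clone():
    norm, meta = _two_group_norm()
    meta = meta.copy()
    meta.loc[meta["clone_id"] == "a2", "clone_id"] = "a1"  # one A clone left
    de = ims.differential_expression(norm, meta, 0, groups=("A", "B"))
    with pytest.raises(ValidationError, match="2 clones"):
        ims.core_signature(de, norm, meta)


def test_recurrence_matches_brute_force():
    rng = np.random.default_rng(9)
    genes = [f"g{i}" for i in range(100)]
    timepoints = [0, 6, 10, 16]
    tables = []
    sig_sets = {}
    for t in timepoints:
        sig = set(rng.choice(genes, size=20, replace=False))
        sig_sets[t] = sig
        de = _de_marking(genes, sig)
        de.timepoint = t
        tables.append(de)
    res = ims.recurrent_genes(tables, "A", min_timepoints=2)
    expected = sorted(
        g for g in genes if sum(g in sig_sets[t] for t in timepoints) >= 2
    )
    assert res.recurrent == expected
    assert set(res.recurrent) <= set().union(*sig_sets.values())
    with pytest.raises(ValidationError):
        ims.recurrent_genes(tables[:1], "A")


def test_planted_gene_recovered(small_normalized, small_config):
    norm, meta, truth = small_normalized
    de = ims.differential_expression(norm, meta, 0, groups=small_config.group_labels)
    planted_b = set(truth.core_genes[small_config.group_labels[1]][0])
    up_b = set(de.up_in(small_config.group_labels[1]))
    assert len(planted_b & up_b) / len(planted_b) >= 0.8
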