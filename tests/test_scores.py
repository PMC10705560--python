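import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import immunosift as ims
from immunosift.io import ValidationError
from conftest import make_norm


def test_module_score_zero_on_constant_matrix():
    values = np.full((6, 50), 1.7)
    norm = make_norm(values)
    res = ims.module_score(norm, [f"g{i}" for i in range(5)], n_bins=5, n_ctrl_per_bin=5, seed=0)
    np.testing.assert_allclose(res.scores, 0.0, atol=1e-12)


def test_module_score_recovers_additive_shift():
    rng = np.random.default_rng(2)
    base = rng.uniform(0.5, 1.5, size=(8, 1))
    values = np.tile(base, (1, 60))
    delta = 0.37
    gene_set = [f"g{i}" for i in range(0, 60, 12)]  # 5 genes spread over bins
    idx = [0, 12, 24, 36, 48]
    values[:, idx] += delta
    res = ims.module_score(make_norm(values), gene_set, n_bins=4, n_ctrl_per_bin=10, seed=1)
    np.testing.assert_allclose(res.scores, delta, atol=1e-12)


def test_module_score_constant_offset_invariance():
    rng = np.random.default_rng(4)
    values = rng.gamma(1.0, 1.0, size=(10, 80))
    gene_set = [f"g{i}" for i in range(7)]
    a = ims.module_score(make_norm(values), gene_set, n_bins=8, n_ctrl_per_bin=6, seed=3)
    b = ims.module_score(make_norm(values + 2.5), gene_set, n_bins=8, n_ctrl_per_bin=6, seed=3)
    assert a.control_genes == b.control_genes
    np.testing.assert_allclose(a.scores, b.scores, atol=1e-12)


def test_module_score_determinism_and_errors(small_normalized):
    norm, meta, truth = small_normalized
    r1 = ims.module_score(norm, truth.m2_genes, seed=11)
    r2 = ims.module_score(norm, truth.m2_genes, seed=11)
    np.testing.assert_array_equal(r1.scores, r2.scores)
    assert r1.control_genes == r2.control_genes
    with pytest.raises(ValidationError):
        ims.module_score(norm, ["not_a_gene"], seed=0)


def _auc(pos, neg):
    import scipy.stats

    u = scipy.stats.mannwhitneyu(pos, neg, alternative="greater").statistic
    return u / (len(pos) * len(neg))


def test_m2_score_separates_planted_macrophages(small_normalized):
    norm, meta, truth = small_normalized
    res = ims.module_score(norm, truth.m2_genes, seed=0)
    scores = pd.Series(res.scores, index=res.cell_ids)
    planted = (meta["cell_type"] == "macrophage") & (meta["group"] == "non_rejected")
    pos = scores[meta.index[planted]]
    neg = scores[meta.index[~planted]]
    assert pos.mean() > neg.mean()
    assert _auc(pos.to_numpy(), neg.to_numpy()) >= 0.95


def test_exhaustion_group_comparison():
    cfg = ims.SyntheticConfig(
        cells_per_clone_per_timepoint=120,
        replicates_per_clone=4,
        n_genes=400,
        timepoints=(0,),
        seed=13,
    )
    ds, truth = ims.generate_scc_experiment(cfg)
    norm = ims.lognormalize(ds)
    res = ims.exhaustion_score(norm, ds.cell_meta, truth.exhaustion_genes, seed=0)
    cmp = ims.replicate_score_comparison(res, ds.cell_meta, groups=cfg.group_labels)
    # exhaustion shift planted in the non-rejected-like group (group B)
    assert cmp["mean_b"] > cmp["mean_a"]
    assert cmp["p_value"] < 0.05


def test_exhaustion_null_mean_difference():
    mix = {"tumor": 0.6, "T_CD8": 0.2, "macrophage": 0.2}
    diffs = []
    for seed in range(8):
        cfg = ims.SyntheticConfig(
            cells_per_clone_per_timepoint=100,
            n_genes=300,
            timepoints=(0,),
            core_log2fc=0.0,
            m2_shift=0.0,
            exhaustion_shift=0.0,
            cell_type_mixture={"rejected": mix, "non_rejected": mix},
            seed=100 + seed,
        )
        ds, truth = ims.generate_scc_experiment(cfg)
        norm = ims.lognormalize(ds)
        res = ims.exhaustion_score(norm, ds.cell_meta, truth.exhaustion_genes, seed=0)
        cmp = ims.replicate_score_comparison(res, ds.cell_meta, groups=cfg.group_labels)
        diffs.append(cmp["mean_b"] - cmp["mean_a"])
    se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
    assert abs(np.mean(diffs)) < 3 * se + 1e-9


def test_cyt_closed_form():
    np.testing.assert_allclose(ims.cytolytic_activity([0.0], [0.0]), [1.0])
    np.testing.assert_allclose(
        ims.cytolytic_activity([3.0], [1.0]), [np.sqrt(8.0)], rtol=1e-12
    )
    rng = np.random.default_rng(6)
    a = rng.uniform(0, 1000, size=1000)
    b = rng.uniform(0, 1000, size=1000)
    np.testing.assert_allclose(
        ims.cytolytic_activity(a, b), np.sqrt((a + 1) * (b + 1)), rtol=1e-12
    )
    with pytest.raises(ValidationError):
        ims.cytolytic_activity([-1.0], [0.0])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    a=st.floats(0, 1e6, allow_nan=False),
    b=st.floats(0, 1e6, allow_nan=False),
    eps=st.floats(1e-6, 10.0),
)
def test_cyt_symmetry_and_monotonicity(a, b, eps):
    ab = ims.cytolytic_activity([a], [b])[0]
    assert ab == pytest.approx(ims.cytolytic_activity([b], [a])[0], rel=1e-12)
    assert ims.cytolytic_activity([a + eps], [b])[0] > ab
    assert ab >= 1.0
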