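import numpy as np
import pandas as pd
import pytest

import immunosift as ims
from immunosift.io import GuideCountTable, ValidationError
from immunosift.screen import (
    NormalizedGuideCounts,
    benjamini_hochberg,
    gene_aggregate,
    guide_test,
    median_normalize,
)


def _guide_table(count_dict, roles=None, conditions=None):
    guides = sorted(count_dict[next(iter(count_dict))].keys()) if isinstance(
        count_dict[next(iter(count_dict))], dict
    ) else None
    samples = list(count_dict)
    n = len(next(iter(count_dict.values())))
    gids = [f"g{i}" for i in range(n)]
    counts = pd.DataFrame({s: count_dict[s] for s in samples}, index=pd.Index(gids, name="guide_id"))
    roles = roles or ["targeting"] * n
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "condition": conditions or ["input" if s.startswith("in") else "endpoint" for s in samples],
            "replicate_id": samples,
        }
    )
    genes = [f"gene{i // 2}" for i in range(n)]
    return GuideCountTable(
        guides=pd.DataFrame({"guide_id": gids, "gene": genes, "role": roles}),
        counts=counts,
        sample_meta=meta,
    )


def test_median_normalize_scale_equivariance():
    base = [10, 20, 30, 40, 55, 70, 85, 100, 130, 160]
    gc = _guide_table({"in1": base, "ep1": [3 * c for c in base]})
    res = median_normalize(gc)
    assert res.size_factors["ep1"] / res.size_factors["in1"] == pytest.approx(3.0, rel=1e-12)
    np.testing.assert_allclose(res.norm["in1"], res.norm["ep1"], rtol=1e-12)

    # identical samples: equal size factors, counts unchanged up to a constant
    gc2 = _guide_table({"in1": base, "in2": base, "ep1": base})
    res2 = median_normalize(gc2)
    assert res2.size_factors.nunique() == 1
    np.testing.assert_allclose(res2.norm["in1"], np.array(base) / res2.size_factors["in1"])


def test_median_normalize_matches_hand_computation():
    rng = np.random.default_rng(8)
    counts = {s: rng.integers(5, 500, size=10).tolist() for s in ["in1", "in2", "ep1"]}
    gc = _guide_table(counts)
    res = median_normalize(gc)
    # independent computation of the median-of-ratios definition
    mat = np.array([counts[s] for s in ["in1", "in2", "ep1"]], dtype=float).T
    ref = np.exp(np.mean(np.log(mat), axis=1))
    expected = np.median(mat / ref[:, None], axis=0)
    np.testing.assert_allclose(
        res.size_factors[["in1", "in2", "ep1"]].to_numpy(), expected, rtol=1e-12
    )


def test_median_normalize_rejects_all_zero_sample():
    gc = _guide_table({"in1": [1, 2, 3, 4], "ep1": [0, 0, 0, 0]})
    with pytest.raises(ValidationError, match="all-zero"):
        median_normalize(gc)


def _norm_fixture(inputs, endpoint):
    n = len(endpoint)
    gids = [f"g{i}" for i in range(n)]
    cols = {f"in{j+1}": np.asarray(v, float) for j, v in enumerate(inputs)}
    cols["ep"] = np.asarray(endpoint, float)
    norm = pd.DataFrame(cols, index=pd.Index(gids, name="guide_id"))
    guides = pd.DataFrame({"guide_id": gids, "gene": [f"gene{i}" for i in range(n)], "role": "targeting"})
    meta = pd.DataFrame(
        {
            "sample_id": list(cols),
            "condition": ["input"] * len(inputs) + ["endpoint"],
            "replicate_id": list(cols),
        }
    )
    return NormalizedGuideCounts(norm=norm, size_factors=pd.Series(1.0, index=list(cols)), guides=guides, sample_meta=meta)


def test_guide_test_central_value_and_antisymmetry():
    rng = np.random.default_rng(3)
    base = rng.integers(50, 500, size=30).astype(float)
    gcn = _norm_fixture([base * 0.9, base, base * 1.1], base)
    res = guide_test(gcn, "ep", ["in1", "in2", "in3"])
    # endpoint equal to the input mean: no fold change, far from significance
    np.testing.assert_allclose(res["lfc"], 0.0, atol=1e-12)
    assert (res["p_value"] > 0.5).all()

    # noiseless swap of roles flips the LFC sign exactly
    a, b = base, base * 4
    fwd = guide_test(_norm_fixture([a, a], b), "ep", ["in1", "in2"])
    rev = guide_test(_norm_fixture([b, b], a), "ep", ["in1", "in2"])
    np.testing.assert_allclose(fwd["lfc"], -rev["lfc"], rtol=1e-12)


def test_guide_test_requires_replicates_and_flags_unrecovered():
    base = np.array([100.0, 0.0, 50.0])
    gcn = _norm_fixture([base, base + 1], base)
    with pytest.raises(ValidationError, match="input replicates"):
        guide_test(gcn, "ep", ["in1"])
    res = guide_test(gcn, "ep", ["in1", "in2"])
    assert res["tested"].tolist() == [True, True, True]
    zero = _norm_fixture([np.array([0.0, 10.0]), np.array([0.0, 12.0])], np.array([5.0, 11.0]))
    res0 = guide_test(zero, "ep", ["in1", "in2"])
    assert not res0["tested"].iloc[0] and np.isnan(res0["p_value"].iloc[0])


def test_benjamini_hochberg_matches_step_up():
    np.testing.assert_allclose(
        benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(benjamini_hochberg([0.37]), [0.37])
    with pytest.raises(ValidationError):
        benjamini_hochberg([1.2])

    def brute(p):
        p = np.asarray(p)
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            adj[i] = running
        return adj

    rng = np.random.default_rng(12)
    for _ in range(50):
        p = rng.uniform(size=rng.integers(1, 40))
        np.testing.assert_allclose(benjamini_hochberg(p), brute(p), rtol=1e-12)


def test_gene_aggregate_top_ranked_gene_and_median_lfc():
    rng = np.random.default_rng(7)
    n = 800
    gids = [f"g{i}" for i in range(n)]
    genes = ["hit"] * 4 + ["lone"] * 4 + [f"gene{i // 4}" for i in range(8, n)]
    p = rng.uniform(0.05, 1.0, size=n)
    lfc = rng.normal(0, 0.2, size=n)
    p[:4] = [1e-9, 2e-9, 3e-9, 4e-9]  # the hit's guides hold the 4 best ranks
    lfc[:4] = [-3.0, -2.5, -2.0, -1.5]
    lfc[4:8] = [-3.0, 0.0, 0.0, 0.0]  # one strong guide does not carry a gene
    gr = pd.DataFrame(
        {"gene": genes, "lfc": lfc, "p_value": p, "tested": True},
        index=pd.Index(gids, name="guide_id"),
    )
    res = gene_aggregate(gr, n_permutations=10_000, seed=0)
    assert res.loc["hit", "gene_p_depleted"] <= 1e-3
    assert res.loc["lone", "median_lfc"] == 0.0  # median of (-3, 0, 0, 0)
    with pytest.raises(ValidationError):
        gene_aggregate(gr, n_permutations=10)


def test_screen_controls_report():
    effects = {f"Pten_g{j}": 4.0 for j in (1, 2, 3, 4)}
    gc, _ = ims.generate_screen_counts(planted_effects=effects, depth=1000, seed=4)
    res = ims.run_screen(gc, n_permutations=1000, seed=4, pooled_endpoint=True)
    diag = ims.screen_report(res, gc)
    pten = diag.control_genes.query("gene == 'Pten'")
    assert (pten["n_called_expected"] == 4).all()
    assert (diag.non_targeting["fraction_called"] <= 0.05).all()
    assert (diag.recovery_fraction > 0.9).all()
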