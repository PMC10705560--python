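"""Pooled CRISPR screen statistics.

Endpoint sgRNA libraries are compared with the input library: counts are
median-of-ratios normalized, each guide's endpoint count is tested against
a negative-binomial null whose mean is the input-replicate mean and whose
dispersion is a trended estimate pooled across guides, and guides are
aggregated to genes by permutation-calibrated robust rank aggregation.
Calls require FDR-adjusted p < 0.05 and |log2 fold change| > 1 at the
guide level (|median LFC| > 1 at the gene level). Control diagnostics
summarize the expected behavior of depletion / enrichment / non-targeting
guides and per-sample guide recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
from statsmodels.stats.multitest import multipletests

from immunosift.io import GuideCountTable, ValidationError

__all__ = [
    "NormalizedGuideCounts",
    "ScreenResult",
    "ControlDiagnostics",
    "median_normalize",
    "guide_test",
    "gene_aggregate",
    "benjamini_hochberg",
    "run_screen",
    "screen_report",
]

DISPERSION_FLOOR = 0.01


@dataclass
class NormalizedGuideCounts:
    """Median-of-ratios normalized guide counts plus the size factors used."""

    norm: pd.DataFrame  # guides x samples, float
    size_factors: pd.Series
    guides: pd.DataFrame
    sample_meta: pd.DataFrame

    def samples(self, condition: str) -> list[str]:
        sm = self.sample_meta
        return list(sm.loc[sm["condition"] == condition, "sample_id"])


@dataclass
class ScreenResult:
    guide_tables: dict[str, pd.DataFrame]  # per endpoint sample
    gene_tables: dict[str, pd.DataFrame]
    size_factors: pd.Series
    recovery_fraction: pd.Series
    fdr: float
    lfc_threshold: float

    def mean_guide_lfc(self) -> pd.Series:
        """Average guide LFC across endpoint samples (screen-wide ranking)."""
        lfcs = pd.concat(
            {s: t["lfc"] for s, t in self.guide_tables.items()}, axis=1
        )
        return lfcs.mean(axis=1)


@dataclass
class ControlDiagnostics:
    control_genes: pd.DataFrame  # per endpoint x control gene
    non_targeting: pd.DataFrame  # per endpoint
    recovery_fraction: pd.Series


def median_normalize(gc: GuideCountTable) -> NormalizedGuideCounts:
    """Median-of-ratios normalization of guide counts.

    The pseudo-reference is the geometric mean across samples over guides
    with nonzero counts in every sample; each sample's size factor is the
    median ratio of its counts to the reference over those guides.
    Normalized count = count / size factor. Exactly proportional samples
    get exactly proportional size factors; scaling one of S samples by c
    rescales the normalized matrix only by a global c^(1/S) (the reference
    moves), so relative guide abundances are invariant.
    """
    counts = gc.counts.to_numpy(dtype=float)
    if (counts.sum(axis=0) == 0).any():
        bad = gc.counts.columns[counts.sum(axis=0) == 0].tolist()
        raise ValidationError(f"sample(s) with all-zero counts: {bad}")
    allpos = (counts > 0).all(axis=1)
    if not allpos.any():
        raise ValidationError("no guide has nonzero counts in every sample; cannot normalize")
    logc = np.log(counts[allpos])
    ref = np.exp(logc.mean(axis=1))
    sf = np.median(counts[allpos] / ref[:, None], axis=0)
    norm = pd.DataFrame(
        counts / sf[None, :], index=gc.counts.index, columns=gc.counts.columns
    )
    return NormalizedGuideCounts(
        norm=norm,
        size_factors=pd.Series(sf, index=gc.counts.columns, name="size_factor"),
        guides=gc.guides.copy(),
        sample_meta=gc.sample_meta.copy(),
    )


def _trended_dispersion(inp: np.ndarray) -> float:
    """Single trended NB dispersion from input-replicate variability.

    Method-of-moments excess variance (s² − μ) regressed through the origin
    on μ² across guides, floored at ``DISPERSION_FLOOR``.
    """
    n = inp.shape[1]
    mu = inp.mean(axis=1)
    s2 = inp.var(axis=1, ddof=1)
    ok = mu > 0
    # mu^2 is estimated by mu_hat^2 - s2/n (E[mu_hat^2] = mu^2 + sigma^2/n);
    # a ratio of sums avoids the attenuation a mu^2-weighted regression
    # suffers when the means are noisy
    denom = float((mu[ok] ** 2 - s2[ok] / n).sum())
    if denom <= 0:
        return DISPERSION_FLOOR
    phi = float((s2[ok] - mu[ok]).sum() / denom)
    return max(phi, DISPERSION_FLOOR)


def guide_test(
    gc_norm: NormalizedGuideCounts,
    endpoint_sample: str,
    input_samples: list[str] | None = None,
    n_endpoint_pool: int = 1,
) -> pd.DataFrame:
    """Per-guide NB enrichment/depletion test of one endpoint vs the inputs.

    Under the NB model (variance μ + φμ², φ a trended estimate pooled
    across guides from input-replicate variability), both the endpoint
    count and the estimated input mean are noisy; in the gamma limit their
    ratio T = (endpoint+0.5)/(μ̂+0.5) follows an F distribution with
    2/cv²(endpoint) and 2/cv²(μ̂) degrees of freedom, where
    cv² = φ + 1/μ and the mean of n replicates divides cv² by n. The
    two-sided p doubles the smaller F tail (capped at 1), so the sampling
    error of the estimated mean does not inflate the type-I error.
    LFC = log2((endpoint+0.5)/(μ+0.5)). Guides with zero counts in all
    input replicates are reported untested (unrecovered in the input
    library). ``n_endpoint_pool`` > 1 marks the endpoint column as the
    mean of that many replicates, shrinking its modeled variance
    accordingly.
    """
    if input_samples is None:
        input_samples = gc_norm.samples("input")
    if len(input_samples) < 2:
        raise ValidationError("need >= 2 input replicates to estimate dispersion")
    if endpoint_sample not in gc_norm.norm.columns:
        raise ValidationError(f"unknown endpoint sample: {endpoint_sample}")
    inp = gc_norm.norm[input_samples].to_numpy(dtype=float)
    end = gc_norm.norm[endpoint_sample].to_numpy(dtype=float)

    phi = _trended_dispersion(inp)
    n_in = inp.shape[1]
    mu = inp.mean(axis=1)
    tested = mu > 0

    lfc = np.log2((end + 0.5) / (mu + 0.5))
    pvals = np.full(len(mu), np.nan)
    m = mu[tested]
    x = end[tested]
    cv2_end = (phi + 1.0 / m) / n_endpoint_pool
    cv2_mu = cv2_end / n_in
    t_ratio = (x + 0.5) / (m + 0.5)
    d1, d2 = 2.0 / cv2_end, 2.0 / cv2_mu
    lower = scipy.stats.f.cdf(t_ratio, d1, d2)
    upper = scipy.stats.f.sf(t_ratio, d1, d2)
    pvals[tested] = np.minimum(1.0, 2.0 * np.minimum(lower, upper))

    return pd.DataFrame(
        {
            "gene": gc_norm.guides.set_index("guide_id")["gene"].reindex(gc_norm.norm.index),
            "role": gc_norm.guides.set_index("guide_id")["role"].reindex(gc_norm.norm.index),
            "mean_input": mu,
            "endpoint": end,
            "lfc": lfc,
            "p_value": pvals,
            "tested": tested,
            "dispersion": phi,
        },
        index=gc_norm.norm.index,
    )


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _rra_scores(normalized_ranks: np.ndarray) -> float:
    """Robust-rank-aggregation rho for one gene: min over j of the Beta(j,
    k−j+1) CDF at the j-th smallest normalized guide rank."""
    r = np.sort(normalized_ranks)
    k = len(r)
    j = np.arange(1, k + 1)
    return float(np.min(scipy.special.betainc(j, k - j + 1, r)))


def _null_rho(n: int, k: int, n_permutations: int, rng: np.random.Generator) -> np.ndarray:
    """Null rho distribution: random size-k subsets of the n normalized ranks."""
    vals = np.arange(1, n + 1) / n
    out = np.empty(n_permutations)
    chunk = max(1, int(2e6 // n))
    j = np.arange(1, k + 1)
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        u = rng.random((b, n))
        idx = np.argpartition(u, k - 1, axis=1)[:, :k]
        r = np.sort(vals[idx], axis=1)
        rho = scipy.special.betainc(j, k - j + 1, r).min(axis=1)
        out[done : done + b] = rho
        done += b
    return out


def gene_aggregate(
    guide_results: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-calibrated robust rank aggregation of guides to genes.

    For each direction, guides are ranked by their one-sided p-value; a
    gene's rho score rewards consistently top-ranked guides, and its
    gene-level p is the fraction of random same-size guide sets scoring at
    least as well ((r+1)/(B+1) convention). A gene's median LFC is the
    median over its tested guides. Genes with no tested guides are
    reported untested (NaN p-values).
    """
    if n_permutations < 1000:
        raise ValidationError("n_permutations must be >= 1000")
    rng = np.random.default_rng(seed)
    res = guide_results[guide_results["tested"]].copy()
    n = len(res)
    if n == 0:
        raise ValidationError("no tested guides to aggregate")

    p_two = res["p_value"].to_numpy()
    lfc = res["lfc"].to_numpy()
    one_sided = {
        "depleted": np.where(lfc < 0, p_two / 2.0, 1.0 - p_two / 2.0),
        "enriched": np.where(lfc > 0, p_two / 2.0, 1.0 - p_two / 2.0),
    }

    genes = sorted(guide_results["gene"].unique())
    rows: dict[str, dict] = {
        g: {
            "n_guides": int((guide_results["gene"] == g).sum()),
            "n_tested": 0,
            "median_lfc": np.nan,
            "gene_p_depleted": np.nan,
            "gene_p_enriched": np.nan,
        }
        for g in genes
    }
    gene_of = res["gene"].to_numpy()
    for g in genes:
        mask = gene_of == g
        if mask.any():
            rows[g]["n_tested"] = int(mask.sum())
            rows[g]["median_lfc"] = float(np.median(lfc[mask]))

    null_cache: dict[int, np.ndarray] = {}
    for direction, p_one in one_sided.items():
        order = np.argsort(p_one, kind="stable")
        ranks = np.empty(n, dtype=float)
        ranks[order] = np.arange(1, n + 1)
        ranks /= n
        for g in genes:
            mask = gene_of == g
            k = int(mask.sum())
            if k == 0:
                continue
            rho = _rra_scores(ranks[mask])
            if k not in null_cache:
                null_cache[k] = _null_rho(n, k, n_permutations, rng)
            p = (1 + int((null_cache[k] <= rho).sum())) / (n_permutations + 1)
            rows[g][f"gene_p_{direction}"] = p

    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene")


def run_screen(
    gc: GuideCountTable,
    fdr: float = 0.05,
    lfc_threshold: float = 1.0,
    n_permutations: int = 10_000,
    seed: int = 0,
    pooled_endpoint: bool = False,
) -> ScreenResult:
    """Full screen analysis: normalize, test each endpoint, aggregate genes.

    Each endpoint sample (mouse) is tested separately against the pooled
    input replicates, matching per-replicate reporting; ``pooled_endpoint``
    instead averages normalized endpoint counts into one comparison.
    """
    gcn = median_normalize(gc)
    endpoints = gcn.samples("endpoint")
    inputs = gcn.samples("input")
    pool = len(endpoints) if pooled_endpoint else 1
    if pooled_endpoint:
        pooled = gcn.norm[endpoints].mean(axis=1)
        gcn.norm = gcn.norm.copy()
        gcn.norm["pooled_endpoint"] = pooled
        gcn.sample_meta = pd.concat(
            [
                gcn.sample_meta,
                pd.DataFrame(
                    [{"sample_id": "pooled_endpoint", "condition": "endpoint", "replicate_id": "pooled"}]
                ),
            ],
            ignore_index=True,
        )
        endpoints = ["pooled_endpoint"]

    guide_tables: dict[str, pd.DataFrame] = {}
    gene_tables: dict[str, pd.DataFrame] = {}
    for i, ep in enumerate(endpoints):
        gt = guide_test(gcn, ep, inputs, n_endpoint_pool=pool)
        padj = np.full(len(gt), np.nan)
        tested = gt["tested"].to_numpy()
        padj[tested] = benjamini_hochberg(gt.loc[tested, "p_value"].to_numpy())
        gt["p_adj"] = padj
        gt["call"] = np.select(
            [
                (padj < fdr) & (gt["lfc"].to_numpy() < -lfc_threshold),
                (padj < fdr) & (gt["lfc"].to_numpy() > lfc_threshold),
            ],
            ["depleted", "enriched"],
            default="ns",
        )
        guide_tables[ep] = gt

        ga = gene_aggregate(gt, n_permutations=n_permutations, seed=seed + i)
        for direction in ("depleted", "enriched"):
            p = ga[f"gene_p_{direction}"].to_numpy()
            adj = np.full(len(p), np.nan)
            ok = ~np.isnan(p)
            adj[ok] = benjamini_hochberg(p[ok])
            ga[f"gene_fdr_{direction}"] = adj
        med = ga["median_lfc"].to_numpy()
        ga["call"] = np.select(
            [
                (ga["gene_fdr_depleted"].to_numpy() < fdr) & (med < -lfc_threshold),
                (ga["gene_fdr_enriched"].to_numpy() < fdr) & (med > lfc_threshold),
            ],
            ["depleted", "enriched"],
            default="ns",
        )
        gene_tables[ep] = ga

    raw = gc.counts
    recovery = (raw > 0).mean(axis=0).rename("recovery_fraction")
    return ScreenResult(
        guide_tables=guide_tables,
        gene_tables=gene_tables,
        size_factors=gcn.size_factors,
        recovery_fraction=recovery,
        fdr=fdr,
        lfc_threshold=lfc_threshold,
    )


def screen_report(result: ScreenResult, gc: GuideCountTable) -> ControlDiagnostics:
    """Control-guide diagnostics per endpoint sample.

    For each depletion / enrichment control gene: how many of its guides
    were called in the expected direction. For non-targeting guides: mean
    |LFC| and fraction called (expected ≈ 0). Plus per-sample recovery.
    """
    expected = {"depletion_control": "depleted", "enrichment_control": "enriched"}
    ctrl_rows = []
    nt_rows = []
    for ep, gt in result.guide_tables.items():
        for role, want in expected.items():
            sub = gt[gt["role"] == role]
            for gene, gsub in sub.groupby("gene"):
                ctrl_rows.append(
                    {
                        "endpoint": ep,
                        "gene": gene,
                        "role": role,
                        "expected_call": want,
                        "n_guides": len(gsub),
                        "n_called_expected": int((gsub["call"] == want).sum()),
                    }
                )
        nt = gt[gt["role"] == "non_targeting"]
        if len(nt):
            nt_rows.append(
                {
                    "endpoint": ep,
                    "n_guides": len(nt),
                    "mean_abs_lfc": float(nt["lfc"].abs().mean()),
                    "fraction_called": float((nt["call"] != "ns").mean()),
                }
            )
    return ControlDiagnostics(
        control_genes=pd.DataFrame(ctrl_rows),
        non_targeting=pd.DataFrame(nt_rows),
        recovery_fraction=result.recovery_fraction,
    )
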