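"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the design of the tumor-rejection study: a handful
of genetically homogeneous single-cell-derived clones split into a rejected
and a non-rejected group, profiled by scRNA-seq at several days
post-inoculation, with group-dependent immune composition (macrophages
enriched in the non-rejected-like group), group-consistent planted
differentially expressed genes (a subset recurring across timepoints), a
pooled CRISPR guide library with targeting / non-targeting /
depletion-control / enrichment-control members, and a survival cohort whose
hazard depends on a median-split covariate.

Counts are negative-binomial (gamma-Poisson) with a single global
dispersion; per-cell library sizes are log-normal. Planted effects are
multiplicative on the expected counts: core genes by 2^LFC in tumor cells
of their group (with small clone-level jitter so the core-signature
consistency rule is non-trivially exercised), module-score shifts on the
designated cell types. All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from immunosift.io import (
    ExpressionDataset,
    GuideCountTable,
    SurvivalTable,
    ValidationError,
    VariantTable,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "CELL_TYPES",
    "default_library_design",
    "generate_scc_experiment",
    "generate_variant_table",
    "generate_screen_counts",
    "generate_survival_cohort",
]

CELL_TYPES = ("tumor", "T_CD8", "T_CD4", "Treg", "macrophage", "monocyte", "DC", "NK")

# Rejected-like group: richer T-cell compartment. Non-rejected-like group:
# macrophage-skewed myeloid compartment (0.12 vs 0.05 of all cells).
DEFAULT_MIXTURE: dict[str, dict[str, float]] = {
    "rejected": {
        "tumor": 0.60,
        "T_CD8": 0.12,
        "T_CD4": 0.06,
        "Treg": 0.03,
        "macrophage": 0.05,
        "monocyte": 0.06,
        "DC": 0.04,
        "NK": 0.04,
    },
    "non_rejected": {
        "tumor": 0.65,
        "T_CD8": 0.05,
        "T_CD4": 0.04,
        "Treg": 0.03,
        "macrophage": 0.12,
        "monocyte": 0.05,
        "DC": 0.03,
        "NK": 0.03,
    },
}


def _gene_names(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n)]


@dataclass
class SyntheticConfig:
    """Study-design parameters for the synthetic scRNA-seq experiment.

    Defaults mirror the modeled study: 2 rejected-like vs 3
    non-rejected-like clones, timepoints 0/6/10/16 days post-inoculation,
    400 cells per clone per timepoint split over 2 replicates, 2000 genes,
    10 planted core genes per group per timepoint at log2 fold change 1.5
    of which a 0.7 fraction recur at every timepoint.
    """

    n_clones_group_a: int = 2  # rejected-like
    n_clones_group_b: int = 3  # non-rejected-like
    group_labels: tuple[str, str] = ("rejected", "non_rejected")
    timepoints: tuple[int, ...] = (0, 6, 10, 16)
    cells_per_clone_per_timepoint: int = 400
    replicates_per_clone: int = 2
    n_genes: int = 2000
    n_core_genes: int = 10
    core_log2fc: float = 1.5
    recurrent_fraction: float = 0.7
    clone_lfc_jitter: float = 0.1
    cell_type_mixture: dict[str, dict[str, float]] | None = None
    nb_dispersion: float = 0.5
    depth_mean: float = 3000.0
    depth_sigma: float = 0.35
    mito_beta: tuple[float, float] = (2.0, 40.0)
    n_m2_genes: int = 100
    n_exhaustion_genes: int = 25
    m2_shift: float = 1.0  # log2, macrophages of group B
    exhaustion_shift: float = 1.0  # log2, CD8 T cells of group B
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_type_mixture is None:
            self.cell_type_mixture = {
                self.group_labels[0]: dict(DEFAULT_MIXTURE["rejected"]),
                self.group_labels[1]: dict(DEFAULT_MIXTURE["non_rejected"]),
            }
        for grp, mix in self.cell_type_mixture.items():
            tot = sum(mix.values())
            if not math.isclose(tot, 1.0, abs_tol=1e-8):
                raise ValidationError(f"cell_type_mixture for {grp} sums to {tot}, not 1")
        for name in (
            "n_clones_group_a",
            "n_clones_group_b",
            "cells_per_clone_per_timepoint",
            "replicates_per_clone",
            "n_genes",
            "n_core_genes",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        n_rec = round(self.recurrent_fraction * self.n_core_genes)
        n_planted = 2 * (n_rec + (self.n_core_genes - n_rec) * len(self.timepoints))
        reserved = self.n_m2_genes + self.n_exhaustion_genes
        if n_planted + reserved > self.n_genes:
            raise ValidationError(
                f"planted gene demand ({n_planted} core + {reserved} signature) "
                f"exceeds n_genes={self.n_genes}"
            )

    @property
    def gene_names(self) -> list[str]:
        return _gene_names(self.n_genes)


@dataclass
class GroundTruth:
    """Planted truth emitted alongside each synthetic dataset."""

    core_genes: dict[str, dict[int, list[str]]] = field(default_factory=dict)
    recurrent_genes: dict[str, list[str]] = field(default_factory=dict)
    cell_type_proportions: dict[str, dict[str, float]] = field(default_factory=dict)
    m2_genes: list[str] = field(default_factory=list)
    exhaustion_genes: list[str] = field(default_factory=list)
    guide_effects: dict[str, float] = field(default_factory=dict)
    true_clonal_fraction: float | None = None
    true_vaf: list[float] = field(default_factory=list)
    hazard_ratio: float | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "core_genes": {g: {str(t): v for t, v in d.items()} for g, d in self.core_genes.items()},
            "recurrent_genes": self.recurrent_genes,
            "cell_type_proportions": self.cell_type_proportions,
            "m2_genes": self.m2_genes,
            "exhaustion_genes": self.exhaustion_genes,
            "guide_effects": self.guide_effects,
            "true_clonal_fraction": self.true_clonal_fraction,
            "hazard_ratio": self.hazard_ratio,
            "extras": {k: v for k, v in self.extras.items() if _jsonable(v)},
        }


def _jsonable(v: Any) -> bool:
    return isinstance(v, (int, float, str, bool, list, dict, type(None)))


# ---------------------------------------------------------------------------
# scRNA-seq experiment


def generate_scc_experiment(config: SyntheticConfig | None = None) -> tuple[ExpressionDataset, GroundTruth]:
    """Simulate the clone x timepoint scRNA-seq experiment.

    Gene means come from a log-normal baseline shared by all clones; planted
    core genes are multiplied by 2^LFC (with per-clone jitter) in tumor
    cells of their group at their planted timepoints; cell types are
    multinomial from the group mixture; counts are NB around log-normal
    per-cell library sizes.
    """
    cfg = config if config is not None else SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_names
    grp_a, grp_b = cfg.group_labels

    # reserve signature gene sets, then plant core genes in the remainder
    pool = rng.permutation(cfg.n_genes)
    m2_idx = pool[: cfg.n_m2_genes]
    exh_idx = pool[cfg.n_m2_genes : cfg.n_m2_genes + cfg.n_exhaustion_genes]
    free = list(pool[cfg.n_m2_genes + cfg.n_exhaustion_genes :])

    n_rec = round(cfg.recurrent_fraction * cfg.n_core_genes)
    n_single = cfg.n_core_genes - n_rec
    core: dict[str, dict[int, list[int]]] = {grp_a: {}, grp_b: {}}
    recurrent: dict[str, list[int]] = {}
    cursor = 0
    for grp in (grp_a, grp_b):
        rec = free[cursor : cursor + n_rec]
        cursor += n_rec
        recurrent[grp] = rec
        for t in cfg.timepoints:
            singles = free[cursor : cursor + n_single]
            cursor += n_single
            core[grp][t] = sorted(rec + singles)

    # per-(clone, gene) jittered LFC: lfc * (1 + U(-j, j))
    clones = [f"{grp_a}_c{i + 1}" for i in range(cfg.n_clones_group_a)] + [
        f"{grp_b}_c{i + 1}" for i in range(cfg.n_clones_group_b)
    ]
    clone_group = {c: (grp_a if c.startswith(grp_a) else grp_b) for c in clones}
    jitter = {
        c: 1.0 + rng.uniform(-cfg.clone_lfc_jitter, cfg.clone_lfc_jitter, size=cfg.n_genes)
        for c in clones
    }

    base_w = rng.lognormal(mean=0.0, sigma=1.2, size=cfg.n_genes)
    base_p = base_w / base_w.sum()
    type_names = list(CELL_TYPES)

    blocks: list[np.ndarray] = []
    meta_rows: list[dict] = []
    inv_disp = 1.0 / cfg.nb_dispersion
    mu_log = math.log(cfg.depth_mean) - cfg.depth_sigma**2 / 2.0

    for clone in clones:
        grp = clone_group[clone]
        mix = cfg.cell_type_mixture[grp]
        probs = np.array([mix.get(t, 0.0) for t in type_names])
        for t in cfg.timepoints:
            n_cells = cfg.cells_per_clone_per_timepoint
            types = rng.choice(len(type_names), size=n_cells, p=probs)
            libsize = rng.lognormal(mean=mu_log, sigma=cfg.depth_sigma, size=n_cells)
            rel = np.tile(base_p, (n_cells, 1))
            tumor = types == type_names.index("tumor")
            planted = np.array(core[grp][t], dtype=int)
            if planted.size and tumor.any():
                factor = 2.0 ** (cfg.core_log2fc * jitter[clone][planted])
                rel[np.ix_(tumor, planted)] *= factor
            if grp == grp_b:
                mac = types == type_names.index("macrophage")
                if cfg.m2_shift and mac.any():
                    rel[np.ix_(mac, m2_idx)] *= 2.0**cfg.m2_shift
                cd8 = types == type_names.index("T_CD8")
                if cfg.exhaustion_shift and cd8.any():
                    rel[np.ix_(cd8, exh_idx)] *= 2.0**cfg.exhaustion_shift
            mu = rel * libsize[:, None]
            lam = rng.gamma(shape=inv_disp, scale=cfg.nb_dispersion * mu)
            blocks.append(rng.poisson(lam).astype(np.int32))
            pct_mito = rng.beta(*cfg.mito_beta, size=n_cells)
            reps = np.arange(n_cells) % cfg.replicates_per_clone + 1
            for i in range(n_cells):
                meta_rows.append(
                    {
                        "cell_id": f"{clone}_t{t}_r{reps[i]}_c{i:04d}",
                        "clone_id": clone,
                        "group": grp,
                        "timepoint": t,
                        "replicate_id": f"{clone}_t{t}_r{reps[i]}",
                        "cell_type": type_names[types[i]],
                        "pct_mito": float(pct_mito[i]),
                    }
                )

    counts = np.vstack(blocks)
    meta = pd.DataFrame(meta_rows).set_index("cell_id")
    ds = ExpressionDataset(counts=counts, gene_names=genes, cell_meta=meta)

    truth = GroundTruth(
        core_genes={
            g: {t: sorted(genes[i] for i in idx) for t, idx in d.items()} for g, d in core.items()
        },
        recurrent_genes={g: sorted(genes[i] for i in idx) for g, idx in recurrent.items()},
        cell_type_proportions={g: dict(m) for g, m in cfg.cell_type_mixture.items()},
        m2_genes=sorted(genes[i] for i in m2_idx),
        exhaustion_genes=sorted(genes[i] for i in exh_idx),
        extras={"m2_shift_group": grp_b, "exhaustion_shift_group": grp_b},
    )
    return ds, truth


# ---------------------------------------------------------------------------
# variants


def generate_variant_table(
    n_variants: int = 500,
    clonal_fraction_target: float = 0.9,
    depth: int = 100,
    seed: int = 0,
) -> tuple[VariantTable, GroundTruth]:
    """Simulate variant read support with a planted clonal fraction.

    Clonal variants have true VAF ~ Beta(20, 20) (centered near 0.5, a
    diploid heterozygous clonal peak); subclonal variants true VAF ~
    Uniform(0.02, 0.20). Observed alt reads are Binomial(depth, true VAF).
    """
    if not 0.0 <= clonal_fraction_target <= 1.0:
        raise ValidationError("clonal_fraction_target must lie in [0, 1]")
    if depth < 10:
        raise ValidationError("depth must be >= 10")
    rng = np.random.default_rng(seed)
    n_clonal = int(round(clonal_fraction_target * n_variants))
    true_vaf = np.concatenate(
        [
            rng.beta(20.0, 20.0, size=n_clonal),
            rng.uniform(0.02, 0.20, size=n_variants - n_clonal),
        ]
    )
    order = rng.permutation(n_variants)
    true_vaf = true_vaf[order]
    is_clonal = (np.arange(n_variants) < n_clonal)[order]
    alt = rng.binomial(depth, true_vaf)
    df = pd.DataFrame(
        {
            "variant_id": [f"v{i:04d}" for i in range(n_variants)],
            "alt_reads": alt,
            "total_reads": depth,
        }
    )
    truth = GroundTruth(
        true_clonal_fraction=n_clonal / n_variants,
        true_vaf=[float(v) for v in true_vaf],
        extras={"is_clonal": [bool(b) for b in is_clonal]},
    )
    return VariantTable(df), truth


# ---------------------------------------------------------------------------
# pooled CRISPR screen


def default_library_design(
    n_target_genes: int = 200,
    guides_per_gene: int = 4,
    n_non_targeting: int = 5,
    depletion_controls: tuple[str, ...] = ("Cd47", "Adar", "Cd274"),
    enrichment_controls: tuple[str, ...] = ("Pten", "Ccar1"),
) -> pd.DataFrame:
    """Guide library layout: 4 guides/gene targeting members, 5 non-targeting
    guides, and depletion / enrichment control genes with 4 guides each."""
    rows = []
    for i in range(n_target_genes):
        gene = f"gene{i:03d}"
        for j in range(guides_per_gene):
            rows.append({"guide_id": f"{gene}_g{j + 1}", "gene": gene, "role": "targeting"})
    for gene in depletion_controls:
        for j in range(guides_per_gene):
            rows.append({"guide_id": f"{gene}_g{j + 1}", "gene": gene, "role": "depletion_control"})
    for gene in enrichment_controls:
        for j in range(guides_per_gene):
            rows.append({"guide_id": f"{gene}_g{j + 1}", "gene": gene, "role": "enrichment_control"})
    for j in range(n_non_targeting):
        rows.append({"guide_id": f"NTC_g{j + 1}", "gene": "NTC", "role": "non_targeting"})
    return pd.DataFrame(rows)


def generate_screen_counts(
    library_design: pd.DataFrame | None = None,
    planted_effects: dict[str, float] | None = None,
    n_input_reps: int = 3,
    n_endpoint_reps: int = 3,
    depth: float = 1000.0,
    dropout_rate: float = 0.0,
    seed: int = 0,
    dispersion: float = 0.5,
    representation_sigma: float = 0.5,
) -> tuple[GuideCountTable, GroundTruth]:
    """Simulate sgRNA counts for input and endpoint libraries.

    ``depth`` is the expected mean count per guide per sample. Input counts
    are NB around a log-normal library representation; endpoint expected
    abundance is the input abundance times 2^effect, renormalized to the
    same depth, then NB-sampled; a ``dropout_rate`` fraction of guides is
    zeroed at each endpoint independent of effect (in-vivo bottleneck
    losses).
    """
    if depth <= 0:
        raise ValidationError("depth must be positive")
    if not 0.0 <= dropout_rate < 1.0:
        raise ValidationError("dropout_rate must lie in [0, 1)")
    lib = library_design if library_design is not None else default_library_design()
    guide_ids = list(lib["guide_id"])
    effects = dict.fromkeys(guide_ids, 0.0)
    if planted_effects:
        unknown = sorted(set(planted_effects) - set(guide_ids))
        if unknown:
            raise ValidationError(f"effects specified for unknown guide ids: {unknown[:5]}")
        effects.update(planted_effects)
    eff = np.array([effects[g] for g in guide_ids])

    rng = np.random.default_rng(seed)
    n = len(guide_ids)
    w = rng.lognormal(mean=0.0, sigma=representation_sigma, size=n)
    w /= w.sum()
    inv_disp = 1.0 / dispersion

    def nb(mu: np.ndarray) -> np.ndarray:
        lam = rng.gamma(shape=inv_disp, scale=dispersion * mu)
        return rng.poisson(lam)

    data: dict[str, np.ndarray] = {}
    meta_rows = []
    mu_input = depth * n * w
    for r in range(n_input_reps):
        sid = f"input_{r + 1}"
        data[sid] = nb(mu_input)
        meta_rows.append({"sample_id": sid, "condition": "input", "replicate_id": sid})
    a = w * 2.0**eff
    a /= a.sum()
    mu_end = depth * n * a
    for r in range(n_endpoint_reps):
        sid = f"M{r + 3}"  # endpoint mice named M3, M4, ...
        c = nb(mu_end)
        if dropout_rate > 0:
            drop = rng.choice(n, size=int(round(dropout_rate * n)), replace=False)
            c = c.copy()
            c[drop] = 0
        data[sid] = c
        meta_rows.append({"sample_id": sid, "condition": "endpoint", "replicate_id": sid})

    counts = pd.DataFrame(data, index=pd.Index(guide_ids, name="guide_id"))
    gc = GuideCountTable(
        guides=lib[["guide_id", "gene", "role"]].copy(),
        counts=counts,
        sample_meta=pd.DataFrame(meta_rows),
    )
    truth = GroundTruth(
        guide_effects={g: float(e) for g, e in effects.items()},
        extras={"dropout_rate": dropout_rate, "depth": depth},
    )
    return gc, truth


# ---------------------------------------------------------------------------
# survival


def generate_survival_cohort(
    n: int = 300,
    hazard_ratio: float = 1.0,
    censor_rate: float = 0.2,
    seed: int = 0,
    base_rate: float = 0.1,
) -> tuple[SurvivalTable, GroundTruth]:
    """Simulate a survival cohort with a median-split covariate effect.

    Covariate ~ Normal(0, 1); event times are exponential with rate
    ``base_rate`` times ``hazard_ratio`` for subjects at or above the
    covariate median; independent exponential censoring is calibrated to
    yield ``censor_rate`` censored subjects on average.
    """
    if n < 10:
        raise ValidationError("n must be >= 10")
    if hazard_ratio <= 0:
        raise ValidationError("hazard_ratio must be positive")
    if not 0.0 <= censor_rate < 1.0:
        raise ValidationError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    cov = rng.normal(size=n)
    high = cov >= np.median(cov)
    rate = base_rate * np.where(high, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        mean_rate = base_rate * (1.0 + hazard_ratio) / 2.0
        c_rate = mean_rate * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i:04d}" for i in range(n)],
            "time": time,
            "event": event,
            "covariate": cov,
        }
    )
    truth = GroundTruth(
        hazard_ratio=hazard_ratio,
        extras={"censor_rate": censor_rate, "base_rate": base_rate},
    )
    return SurvivalTable(df), truth
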