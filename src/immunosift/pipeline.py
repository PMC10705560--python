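"""End-to-end orchestration: simulate → QC → signatures → scores → screen →
composition → survival, with a consolidated JSON report.

One global seed deterministically derives per-stage seeds (CRC32 of the
stage name XORed into the seed), so any stage rerun alone reproduces its
part of the pipeline. When running on simulated data the report includes a
ground-truth comparison section (core-signature Jaccard, recurrent-gene
recovery, planted-guide rank, survival log-rank p).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import zlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from immunosift import clonality as clon
from immunosift import composition as comp
from immunosift import qc as qcmod
from immunosift import scores as scoremod
from immunosift import screen as screenmod
from immunosift import signatures as sigmod
from immunosift import survival as survmod
from immunosift import synthetic as synth
from immunosift.io import ValidationError

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All stage parameters; defaults are the study's analysis settings."""

    outdir: str = "immunosift_run"
    seed: int = 0
    # QC / normalization
    mito_max: float = 0.10
    sd_k: float = 2.0
    scale_total: float = 10_000.0
    # DE / signatures
    fc_threshold: float = 1.5
    alpha: float = 0.01
    z_threshold: float = 0.1
    min_timepoints: int = 2
    min_pct: float = 0.10
    # clonality
    vaf_threshold: float = 0.25
    n_variants: int = 500
    clonal_fraction_target: float = 0.9
    variant_depth: int = 100
    # screen
    screen_fdr: float = 0.05
    screen_lfc: float = 1.0
    n_permutations: int = 10_000
    screen_depth: float = 1000.0
    screen_dropout: float = 0.0
    strongest_depletion_lfc: float = -8.12
    # survival
    survival_n: int = 300
    survival_hazard_ratio: float = 3.0
    survival_censor_rate: float = 0.2
    # synthetic expression overrides (SyntheticConfig field -> value)
    synthetic: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        checks = [
            (0 <= self.mito_max <= 1, "mito_max must lie in [0, 1]"),
            (self.sd_k > 0, "sd_k must be positive"),
            (self.scale_total > 0, "scale_total must be positive"),
            (self.fc_threshold >= 1, "fc_threshold must be >= 1"),
            (0 < self.alpha <= 1, "alpha must lie in (0, 1]"),
            (0 <= self.vaf_threshold <= 1, "vaf_threshold must lie in [0, 1]"),
            (0 < self.screen_fdr <= 1, "screen_fdr must lie in (0, 1]"),
            (self.min_timepoints >= 1, "min_timepoints must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValidationError(msg)


def _stage_seed(seed: int, stage: str) -> int:
    return (seed ^ zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _jaccard(a, b) -> float:
    a, b = set(a), set(b)
    return len(a & b) / len(a | b) if (a | b) else 1.0


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages on simulated inputs; returns the report dict.

    Stage outputs are written under ``config.outdir`` as TSVs plus a
    ``report.json`` with stage summaries, the parameter echo, seeds, and
    output checksums. A stage failure aborts with the stage name; partial
    outputs are kept next to a ``FAILED`` marker.
    """
    os.makedirs(config.outdir, exist_ok=True)
    report: dict[str, Any] = {
        "parameters": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": {},
        "ground_truth_comparison": {},
    }
    outputs: list[str] = []
    stage = "init"

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        path = os.path.join(config.outdir, name)
        df.to_csv(path, sep="\t", float_format="%.10g", **kw)
        outputs.append(path)

    try:
        # --- simulate ------------------------------------------------------
        stage = "simulate"
        scfg = synth.SyntheticConfig(seed=_stage_seed(config.seed, stage), **config.synthetic)
        ds, truth = synth.generate_scc_experiment(scfg)
        report["stages"][stage] = {"n_cells": ds.n_cells, "n_genes": ds.n_genes}

        # --- qc / normalize ------------------------------------------------
        stage = "qc"
        ds_f, qc_report = qcmod.filter_cells(ds, mito_max=config.mito_max, sd_k=config.sd_k)
        save(qc_report.per_library, "qc_report.tsv", index=False)
        norm = qcmod.lognormalize(ds_f, scale_total=config.scale_total)
        report["stages"][stage] = {
            "n_cells_in": ds.n_cells,
            "n_cells_kept": ds_f.n_cells,
        }

        # --- clonality ------------------------------------------------------
        stage = "clonality"
        vt, vtruth = synth.generate_variant_table(
            n_variants=config.n_variants,
            clonal_fraction_target=config.clonal_fraction_target,
            depth=config.variant_depth,
            seed=_stage_seed(config.seed, stage),
        )
        summary = clon.clonal_fraction(vt, threshold=config.vaf_threshold)
        save(vt.df, "variants.tsv", index=False)
        report["stages"][stage] = {
            "n_variants": summary.n_variants,
            "clonal_fraction": summary.clonal_fraction,
            "threshold": summary.threshold,
        }
        report["ground_truth_comparison"]["clonal_fraction_error"] = abs(
            summary.clonal_fraction - vtruth.true_clonal_fraction
        )

        # --- signatures -----------------------------------------------------
        stage = "signatures"
        meta = ds_f.cell_meta
        groups = scfg.group_labels
        de_tables = []
        jaccards = {}
        for t in scfg.timepoints:
            de = sigmod.differential_expression(
                norm,
                meta,
                timepoint=t,
                groups=groups,
                fc_threshold=config.fc_threshold,
                alpha=config.alpha,
                min_pct=config.min_pct,
            )
            de_tables.append(de)
            save(de.table, f"de_day{t}.tsv")
            core = sigmod.core_signature(de, norm, meta, z_threshold=config.z_threshold)
            detected = {groups[0]: core.core_a_genes, groups[1]: core.core_b_genes}
            jaccards[str(t)] = {
                g: _jaccard(detected[g], truth.core_genes[g][t]) for g in groups
            }
        rec = {g: sigmod.recurrent_genes(de_tables, g, config.min_timepoints) for g in groups}
        save(
            pd.DataFrame(
                [
                    {"group": g, "gene": gene, "timepoints": ",".join(map(str, tps))}
                    for g, r in rec.items()
                    for gene, tps in r.gene_timepoints.items()
                ]
            ),
            "recurrent_genes.tsv",
            index=False,
        )
        report["stages"][stage] = {
            "n_significant_per_timepoint": {str(d.timepoint): len(d.significant()) for d in de_tables},
            "n_recurrent": {g: len(r.recurrent) for g, r in rec.items()},
        }
        report["ground_truth_comparison"]["core_signature_jaccard"] = jaccards
        report["ground_truth_comparison"]["recurrent_jaccard"] = {
            g: _jaccard(rec[g].recurrent, truth.recurrent_genes[g]) for g in groups
        }

        # --- scores ---------------------------------------------------------
        stage = "scores"
        sseed = _stage_seed(config.seed, stage)
        m2 = scoremod.module_score(norm, truth.m2_genes, seed=sseed)
        save(m2.to_frame(), "m2_scores.tsv", index=False)
        exh = scoremod.exhaustion_score(norm, meta, truth.exhaustion_genes, seed=sseed)
        exh_cmp = scoremod.replicate_score_comparison(exh, meta, groups=groups)
        report["stages"][stage] = {
            "m2_score_mean": float(np.mean(m2.scores)),
            "exhaustion_comparison": exh_cmp,
        }

        # --- screen ---------------------------------------------------------
        stage = "screen"
        lib = synth.default_library_design()
        effects = {"Cd47_g2": config.strongest_depletion_lfc}
        effects.update({f"Cd47_g{j}": -4.0 for j in (1, 3, 4)})
        effects.update({f"Pten_g{j}": 4.0 for j in (1, 2, 3, 4)})
        gc, struth = synth.generate_screen_counts(
            lib,
            planted_effects=effects,
            depth=config.screen_depth,
            dropout_rate=config.screen_dropout,
            seed=_stage_seed(config.seed, stage),
        )
        sres = screenmod.run_screen(
            gc,
            fdr=config.screen_fdr,
            lfc_threshold=config.screen_lfc,
            n_permutations=config.n_permutations,
            seed=_stage_seed(config.seed, stage),
        )
        diag = screenmod.screen_report(sres, gc)
        for ep, gt in sres.guide_tables.items():
            save(gt, f"guide_results_{ep}.tsv")
        for ep, ga in sres.gene_tables.items():
            save(ga, f"gene_results_{ep}.tsv")
        save(diag.control_genes, "controls.tsv", index=False)
        mean_lfc = sres.mean_guide_lfc()
        report["stages"][stage] = {
            "size_factors": sres.size_factors.round(4).to_dict(),
            "recovery_fraction": sres.recovery_fraction.round(4).to_dict(),
            "top_depleted_guide": str(mean_lfc.idxmin()),
        }
        report["ground_truth_comparison"]["planted_strongest_guide_ranks_first"] = bool(
            mean_lfc.idxmin() == "Cd47_g2"
        )

        # --- composition ----------------------------------------------------
        stage = "composition"
        pt = comp.cell_type_proportions(ds_f, denominator="immune")
        save(pt, "composition.tsv", index=False)
        comp_tests = {
            str(t): comp.compare_proportions(pt, "macrophage", t, groups=groups)
            for t in scfg.timepoints
        }
        report["stages"][stage] = {"macrophage_tests": comp_tests}

        # --- survival -------------------------------------------------------
        stage = "survival"
        st, struth2 = synth.generate_survival_cohort(
            n=config.survival_n,
            hazard_ratio=config.survival_hazard_ratio,
            censor_rate=config.survival_censor_rate,
            seed=_stage_seed(config.seed, stage),
        )
        labels = survmod.stratify_by_median(st.df["covariate"])
        from immunosift.io import SurvivalTable

        high = SurvivalTable(st.df[labels == "high"])
        low = SurvivalTable(st.df[labels == "low"])
        km_high = survmod.km_estimate(high, "high")
        km_low = survmod.km_estimate(low, "low")
        lr = survmod.logrank_test(high, low)
        save(km_high.to_frame(), "km_high.tsv", index=False)
        save(km_low.to_frame(), "km_low.tsv", index=False)
        report["stages"][stage] = {
            "n_high": len(high.df),
            "n_low": len(low.df),
            "chi_square": lr["chi_square"],
            "p_value": lr["p_value"],
        }
        report["ground_truth_comparison"]["survival_logrank_p"] = lr["p_value"]

    except Exception as exc:
        marker = os.path.join(config.outdir, "FAILED")
        with open(marker, "w") as fh:
            fh.write(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report["outputs"] = {os.path.basename(p): _sha256(p) for p in sorted(outputs)}
    report_path = os.path.join(config.outdir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
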