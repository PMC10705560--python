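"""Per-timepoint differential expression, core signatures, recurrence.

Simulates a two-group clone experiment (rejected vs non-rejected-like)
with 10 planted core genes per group per timepoint, runs QC +
log-normalization, tests tumor cells with the Wilcoxon rank-sum DE rule
(fold change > 1.5, Bonferroni p < 0.01), applies the all-clone z-score
consistency rule, and collects genes recurring at >= 2 timepoints.
"""

import immunosift as ims

cfg = ims.SyntheticConfig(cells_per_clone_per_timepoint=150, n_genes=800, seed=3)
ds, truth = ims.generate_scc_experiment(cfg)
kept, qc_report = ims.filter_cells(ds)
norm = ims.lognormalize(kept)
print(f"cells: {ds.n_cells} simulated, {kept.n_cells} after QC\n")

de_tables = []
for t in cfg.timepoints:
    de = ims.differential_expression(norm, kept.cell_meta, t, groups=cfg.group_labels)
    core = ims.core_signature(de, norm, kept.cell_meta)
    de_tables.append(de)
    planted = set(truth.core_genes[cfg.group_labels[1]][t])
    detected = set(core.core_b_genes)
    print(
        f"day {t:>2}: {len(de.significant()):>3} significant genes, "
        f"core sets {len(core.core_a_genes)}/{len(core.core_b_genes)} (A/B), "
        f"planted-B recovered {len(planted & detected)}/{len(planted)}"
    )

for grp in cfg.group_labels:
    rec = ims.recurrent_genes(de_tables, grp, min_timepoints=2)
    print(f"recurrent in {grp}: {len(rec.recurrent)} genes (planted {len(truth.recurrent_genes[grp])})")

print()
print("Core genes are consistently shifted in EVERY clone of one group;")
print("recurrent genes stay significant across timepoints - stable candidates")
print("for what makes a clone aggressive rather than one-off noise.")
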