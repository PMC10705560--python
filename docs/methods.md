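# Methods

This note documents the statistical procedures implemented in
`immunosift`, the assumptions behind them, the parameters that matter, and
what the synthetic-data generator does and does not emulate.

## Clonality

For each variant, VAF = alt reads / total reads (exact division, full
float precision; the log2 transform is display-only). The clonal fraction
is the proportion of variants with VAF at or above a threshold, default
0.25 — the conventional cutoff separating clonal from subclonal point
mutations in a diploid tumor (a heterozygous clonal variant sits near VAF
0.5; subclonal populations fall below). The boundary is inclusive
(VAF = threshold counts as clonal); `strict=True` switches to a strict
inequality for workflows that draw the boundary the other way. As a
function of the threshold the fraction is a right-continuous,
non-increasing step function.

## Cell QC and normalization

Cells are kept when (i) their mitochondrial read fraction is at most
`mito_max` (default 0.10) and (ii) their detected-gene count lies within
mean ± `sd_k`·SD (default k = 2, SD with denominator n−1) computed within
their library (`per` grouping key, default `replicate_id`; whether a
"library" is a lane or a hashed sample is a data-dependent choice, hence
the knob). The mitochondrial filter is applied first and the SD bounds are
computed on mito-passing cells: dying cells inflate both tails and would
otherwise drag the bounds; `mito_first=False` restores the other order.
The SD rule uses raw detected-gene counts (no log transform). Libraries
with fewer than 3 cells skip the SD rule with a warning, since the SD is
not meaningfully defined.

Normalization is `value = ln(1 + scale_total · count / libsize)` with
`scale_total` = 10,000 — depth-invariant (scaling all counts of a cell
leaves its row unchanged) and strictly monotone in counts within a cell.
All-zero cells map to all-zero rows with a warning.

## Differential expression and signatures

At each timepoint, tumor cells of the two clone groups are compared
gene-by-gene with the two-sided Wilcoxon rank-sum test on log-normalized
values — exact enumeration when both groups have ≤ 25 cells and the gene
has no ties, otherwise the tie-corrected, continuity-corrected normal
approximation (scipy's `mannwhitneyu` implements precisely this). Only
genes detected in ≥ `min_pct` (default 10%) of cells in at least one group
are tested; Bonferroni correction is over the tested genes.
`avg_log2FC = log2((mean expm1 A + 1)/(mean expm1 B + 1))` — the common
single-cell convention of averaging de-logged expression with a
pseudocount of 1. A gene is significant ("up" in a group) when
fold change > 1.5 and Bonferroni p < 0.01. Swapping the group labels
negates every LFC and preserves every p-value exactly.

**Core signature.** Significant genes (both directions) are averaged per
clone over tumor cells, and each gene's per-clone means are scaled to
z-scores across all clones jointly (SD with denominator n−1). A gene is
core for a group iff z > 0.1 in every clone of that group and z < 0 in
every clone of the other. Genes constant across clones (SD = 0) have
undefined z and are excluded and flagged. The procedure refuses to run
with fewer than 2 clones in either group: an all-clone consistency rule is
vacuous for a single clone.

**Recurrence.** A gene is recurrent for a group when it is significantly
up in that group at ≥ `min_timepoints` (default 2) timepoints, using the
same significance rule as the DE table.

## Module scores, exhaustion, CYT

The module score contrasts a gene set against expression-matched
background: genes are ranked by mean normalized expression across the
scored cells and cut into `n_bins` (25) equal-frequency bins, ties broken
by stable gene order; for each member gene, up to `n_ctrl_per_bin` (100)
control genes are sampled without replacement from its bin (members
excluded), and the pooled, deduplicated controls give the background. The
score of a cell is mean(member genes) − mean(pooled controls); it is zero
in expectation for a random gene set, exactly zero on a constant matrix,
and invariant to adding a constant to every gene. Bins with fewer
candidates than requested contribute all of them, with a warning.

The exhaustion score applies the same algorithm to a 25-gene T-cell
dysfunction signature on CD8 T cells only, recomputing bins on those cells
so the background matches the scored population. Group comparisons use
replicate mean scores as the test unit by default (`unit="cell"` exists);
replicate-level testing respects the biological sampling unit and avoids
pseudo-replication across thousands of correlated cells.

CYT = exp((ln(GZMA+1) + ln(PRF1+1))/2) = sqrt((GZMA+1)(PRF1+1)) per bulk
sample: symmetric, ≥ 1, strictly increasing in each input.

Signature gene lists are data: the synthetic configuration carries
placeholder 100-gene M2 and 25-gene exhaustion sets (real marker lists can
be dropped in wherever a gene list is accepted).

## Pooled CRISPR screen

**Normalization** is DESeq-style median-of-ratios: the pseudo-reference is
the geometric mean across samples over guides with nonzero counts in every
sample; a sample's size factor is the median ratio of its counts to the
reference over those guides; normalized count = count / size factor. No
pseudocount enters the ratios, so exact proportional scaling between
samples yields exactly proportional size factors. Scaling one of S samples
by c rescales the reference by c^(1/S), so its size factor picks up
c^(1−1/S) and the normalized matrix a single global factor c^(1/S) —
relative guide abundances are exactly invariant, which is the quantity the
tests consume. An `all-zero sample` is rejected.

**Per-guide test.** The NB model takes Var = μ + φμ². A single trended
dispersion φ is pooled across guides from input-replicate variability: the
method-of-moments excess variance s² − μ̂ summed over guides, divided by
the summed unbiased μ² estimate (μ̂² − s²/n), floored at 0.01. A ratio of
sums is used rather than a μ²-weighted regression because the per-guide
means are themselves noisy at screen-scale dispersions and a noisy
regressor attenuates the slope. With 3 input replicates, per-guide
dispersion estimates would be hopeless; pooling is the only stable choice.

Both the endpoint count and the estimated input mean μ̂ (mean of n
normalized input replicates) are noisy. In the gamma limit of the NB model
their ratio T = (endpoint + 0.5)/(μ̂ + 0.5) follows an F distribution with
2/cv² and 2n/cv² degrees of freedom, cv² = φ + 1/μ̂; the two-sided p
doubles the smaller F tail (capped at 1). This form is used because a
plug-in NB tail at μ̂ ignores the sampling error of μ̂ and demonstrably
inflates the type-I error by a factor ≈ (1+1/n) on the variance scale
(measured rejection at nominal 0.05 ≈ 0.09 with n = 3); the F form
measures 0.04–0.07 across simulation seeds. A consequence of the
continuous approximation is that the p-value at the exact central value is
close to, but not exactly, 1. LFC = log2((endpoint+0.5)/(μ̂+0.5)). Each
endpoint sample (mouse) is tested separately against the pooled inputs by
default, matching per-replicate reporting; `pooled_endpoint=True` averages
the normalized endpoint replicates into a single, more powerful comparison
(its modeled variance shrinks by the pool size). Guides with zero counts
in all input replicates are reported untested (unrecovered).

**Gene aggregation** is permutation-calibrated robust rank aggregation.
Per direction, guides are ranked by one-sided p; a gene with k guides
scores ρ = min over j = 1..k of the Beta(j, k−j+1) CDF at its j-th best
normalized rank — small when several guides rank high, robust to one dead
guide (unlike Fisher combination, which a single p ≈ 1 can poison). The
gene p-value is (1 + #{null ρ ≤ ρ_obs}) / (B + 1) over B (default 10⁴)
random same-size guide sets, so the resolution floor is 1/(B+1).
Benjamini–Hochberg runs across genes per direction; a gene is called when
its FDR < 0.05 and |median guide LFC| > 1 with the matching sign (the same
thresholds apply per guide).

**Diagnostics** report, per endpoint: how many guides of each depletion /
enrichment control gene were called in the expected direction, the mean
|LFC| and called fraction of non-targeting guides (expected ≈ 0), and each
sample's guide recovery fraction.

## Survival

Median stratification labels a subject "high" iff its covariate is at or
above the cohort median (standard midpoint for even n; ties at the median
are high, so a constant covariate is all-high). Kaplan–Meier is the
product-limit estimator; censored subjects leave the risk set after their
time, and when an event and a censoring coincide the event counts first.
The two-group log-rank statistic is (ΣO − ΣE)²/ΣV with the hypergeometric
expectation and variance at each distinct event time, referred to
chi-square with 1 df; on uncensored data the KM curve equals the empirical
survival function exactly. For k > 2 groups the score statistic
Σ(O−E)²/E with k−1 df is provided (`logrank_test_k`); the diagonal
variance approximation is standard for omnibus use, and pairwise two-group
tests remain available for specific contrasts.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the modeled study design: 2 rejected-like + 3
non-rejected-like clones; timepoints 0/6/10/16 days; 400 cells per clone
per timepoint split over 2 replicates (per-clone replicate counts are not
part of the public record; 2 is a modeling choice); 2000 genes with a
shared log-normal baseline; NB (gamma-Poisson) counts with a single global
dispersion 0.5 — the simplest model that still exercises
overdispersion-aware statistics; log-normal library sizes around 3000
counts/cell. Ten core genes per group per timepoint are planted at log2 FC
1.5 in tumor cells only, with ±10% per-clone jitter so the z > 0.1
consistency rule is non-trivially exercised; 70% of each core set recurs
at every timepoint. Cell types are drawn multinomially from group-level
mixtures with macrophages elevated in the non-rejected-like group (0.12 vs
0.05 of all cells) and a richer T-cell compartment in the rejected-like
group; mixtures are constant over time. M2 (+1 log2 on macrophages of the
non-rejected-like group) and exhaustion (+1 log2 on its CD8 cells) shifts
are planted on disjoint placeholder gene sets of 100 and 25 genes.

The screen generator draws a log-normal library representation, NB input
counts at a mean depth per guide (default 1000 — "depth" is per guide per
sample), endpoint abundance = input × 2^effect renormalized to depth, and
an optional effect-independent dropout fraction zeroed per endpoint sample
(the in-vivo bottleneck). The survival generator draws a standard-normal
covariate, exponential event times with the hazard multiplied by the
hazard ratio at or above the covariate median, and independent exponential
censoring calibrated to the target censoring rate. The variant generator
draws clonal true VAFs from Beta(20, 20) and subclonal from
Uniform(0.02, 0.20), observed as Binomial(depth, VAF).

Not emulated: raw reads, hashing barcodes and demultiplexing, doublets,
ambient RNA, batch effects, cell-type-specific expression programs
(labels are assigned directly; clustering is out of scope), per-gene
dispersions, mixtures drifting over time, copy-number effects on guide
counts, or non-proportional hazards. Passing tests therefore demonstrate
correctness of the statistics under a faithful but idealized generative
model, not robustness to every artifact of real data.

## Pipeline, seeds, determinism

`run_pipeline` executes the stages in order under one global seed; each
stage's seed is derived as `(seed XOR crc32(stage name)) mod 2^31`, so a
stage rerun in isolation reproduces its slice of the run. The report
echoes all parameters, summarizes each stage, includes a ground-truth
comparison for simulated runs (single-run recovery quantities — Jaccard of
core/recurrent sets, planted-guide rank, log-rank p; the multi-seed
calibration properties live in the test suite and acceptance script), and
checksums every output file. Identical config + seed give identical
reports.

## Numerical conventions

Wilcoxon: exact only when both n ≤ 25 and no ties. Bonferroni:
min(1, p·m) over tested genes. BH: standard step-up (via statsmodels),
monotone, capped at 1. Degenerate comparisons where every observation is
identical return p = 1. Dispersion floor 0.01 prevents degenerate Poisson
tails. Permutation p-values use the (r+1)/(B+1) convention. TSV floats are
written at 10 significant digits, which round-trips all quantities
produced here.

## Problem sizes

Default test and acceptance runs use the study-scale expression design
(8000 cells × 2000 genes), a 2000-guide null screen and an 825-guide
planted screen over tens of seeds, and 400 + 100 survival cohorts — sizes
chosen so the full suite completes in well under a minute each while
leaving the binomial error of every calibration estimate small against its
acceptance band.
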