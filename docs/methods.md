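# Methods

## The integration procedure

Inputs are two gene-level dependency matrices (genes × screens, log
fold-change-like scores; negative = depleted on knockout) with per-screen
metadata (cell line, institute/batch, tissue lineage, subtype). After gene
symbols are harmonized through a user-supplied alias table and the two
datasets are restricted to shared genes, a full pipeline runs:

1. **Quantile normalization**, per institute. Every screen's non-missing
   values are mapped onto the mean of per-rank sorted values across screens.
   Ties receive the mean of their tied reference positions; screens with
   missing entries are matched through their empirical quantile function, so
   unequal non-missing counts are handled. Note that the reference itself is
   data-dependent: transforming one screen monotonically leaves all ranks
   intact but moves the reference, so only rank structure and cross-screen
   distribution equality are exact invariants.
2. **Screen-quality spline adjustment.** The consensus profile is the
   per-gene average fold change across screens. For each screen a cubic
   regression spline (B-spline basis, ~5 effective degrees of freedom by
   default, one interior knot at the median; `df` configurable) is fitted to
   (consensus, screen score) pairs and the departure from the diagonal,
   f(x) − x, is subtracted. A screen whose phenotype intensity is uniformly
   inflated (score ≈ c·consensus) is thereby pulled back onto the consensus.
   One spline is fitted per screen; fitting is on non-missing entries, but
   masked entries still receive the adjustment at their consensus value.
3. **Empirical-Bayes batch correction** in the location/scale (ComBat)
   family, with batch = institute and no further covariates. The model is
   fitted *only* on cell lines screened by both institutes (screens
   containing missing values are excluded from estimation) and the frozen
   parameters are applied to every screen — the extension that lets screens
   unique to one institute be corrected. Estimation follows the standard
   parametric route: pooled per-gene mean and variance (residual variance
   about per-batch means), per-batch location/scale estimates on
   standardized data, normal and inverse-gamma priors with
   method-of-moments hyperparameters, and the iterative posterior solution
   run to relative tolerance 1e-4. Genes with zero pooled variance are
   excluded and logged. With shrinkage disabled the adjustments reduce
   exactly to the per-batch moments, which is the oracle the tests compare
   against (post-correction batch means agree to < 1e-8 on the fitting set).
4. **Optional second quantile normalization and PC removal** (pipelines
   `combat_qn`, `combat_qn_pc1`, `combat_qn_pc1-2`). For PC removal, screens
   are observations and genes features; missing entries are mean-imputed per
   gene for the decomposition and re-masked afterwards; the projection onto
   the first one or two right-singular vectors is subtracted.
5. **Duplicate resolution.** Each overlapping cell line has one corrected
   screen per institute. Pair distance is 1 − weighted Pearson; the
   divergence threshold is the 95th percentile of distances among pairs that
   are *mutual first neighbors*. Pairs within the threshold are averaged
   gene-wise; divergent pairs keep the screen with the better (more
   negative) NNMD, supplied externally or computed from the reference
   control sets. The result has exactly one column per cell line.

## Similarity and identity recall

Per-gene weights are the absolute mean (across the two institutes) of the
adjusted Fisher–Pearson skewness of the gene's dependency signal over the
overlapping cell lines — selective dependencies carry cell-line identity,
flat profiles do not. Identity recall ranks, for each overlap screen, all
other screens of the union by weighted Pearson (ties broken by screen id
for determinism); each cell line keeps the minimum of its two directional
counterpart ranks, and curve(k) is the fraction of lines with min-rank ≤ k.
nAUC averages the curve over all candidate ranks. Under a label-shuffled
null the *directional* rank is exactly uniform (P(rank ≤ k) = k/(N−1)); the
min-of-two statistic lies between that and the independent-minimum bound
because the two directions are positively correlated.

## Benchmark statistics

- **NNMD** = (mean(E) − mean(N)) / sd(N), per screen; affine-invariant;
  more negative is better.
- **Unexpressed FPR**: fraction of genes unexpressed in the screened line
  (log2(TPM+1) < 0.01) falling in the 15% most-depleted ranks; 0.15 for a
  random screen.
- **Empirical-FDR recall**: unexpressed genes form the null; per-gene
  add-one empirical p-values, Benjamini–Hochberg across genes, recall of
  reference essentials at the chosen FDR.
- **Lineage AMI**: 100 k-means++ clusterings (run-indexed seeds) on the 500
  top-variance genes, adjusted mutual information against lineage labels,
  one-sample t vs 0.
- **NormLRT** = 2·(LL_skew-t − LL_normal) per gene profile. The skew-t
  (Azzalini location/scale/slant/df) likelihood is maximized by Nelder–Mead;
  on failure the df is fixed at 2, 5, 10, 25, 50, 100 in order; the normal
  limit (slant 0, df 1e6) is always a candidate, so the statistic is
  non-negative up to optimizer tolerance.
- **Biomarker associations**: equal-variance two-sided t-tests of carrier
  vs non-carrier dependency per (tissue, CFE, selective gene), ≥3 per group,
  BH-corrected globally across all tests; effect size is Cohen's Δ
  (difference in means over pooled sd). Selective genes are NormLRT > 200
  or an explicit list.
- **Oncogene benchmark**: oncogenes behaving as common essentials (mean
  score < −0.5) are dropped; pooled ROC AUC over (gene, line) pairs with
  gain-of-function lines as positives (expected more negative), per-oncogene
  NNMD for genes with ≥2 positives.
- **Gene-pair recovery**: |Pearson| of each known pair vs a null in which
  the partner is replaced by a random gene from the same mean-score bin (20
  equal-width bins, empty bins fall back to the nearest non-empty one);
  empirical p-values, BH, count at FDR ≤ 0.10 with a bootstrap CI over pair
  resampling. Mean-matching matters because variable screen quality inflates
  correlations between any pair of strongly depleted genes.

## Common-essential calling

**Binary depletion calls** treat each screen as a rank classifier of the
prior-known essential (E) and non-essential (N) controls: at rank k,
PPV(k) = |P(k) ∩ E| / |P(k)| with P(k) the controls among the k most
depleted genes; k* is the largest rank with PPV ≥ 0.95, F* the score at
rank k*, and every gene scoring below F* is called. The implementation is
verified against an exhaustive scan with explicit set arithmetic.

**90th-percentile method**: for each gene, screens are ordered most → least
dependent and the screen at position ceil(0.9·n) is its boundary (the line
where the gene is about as weakly depleted as it ever gets); the gene's
depletion rank within that screen is recorded; a two-component normal
mixture over all genes' ranks is fitted and genes below the density
crossover between the component means are common essentials. The mixture is
a hand-rolled 1-D EM (tolerance 1e-6, ≤500 iterations) started from five
quantile-split initializations, selecting among converged fits by component
separation (Ashman's D). Maximum likelihood alone is *not* a safe selector
here: the upper rank mode is strongly skewed, and a two-Gaussian fit can
gain more likelihood by splitting that bulk than by isolating a small
depleted component; the separation criterion keeps the lower component on
the depleted minority. Ranks are used raw, and the procedure is invariant
to adding a constant to every score.

**Never-expressed negatives** apply the same machinery to the basal
expression matrix: with expression as the score, the boundary line is the
gene's 90th-percentile *most expressed* line and low within-line ranks mean
low expression, so the genes below the crossover are those still silent in
their near-top expression line. (Orientation conventions differ between
implementations of this procedure; in this package raw expression — not its
negation — produces that semantics.)

**ADaM consensus**: per tissue, the threshold n* (cell lines required to
call a gene tissue-essential) maximizes TPR(n) − expected_rate(n), with TPR
on the reference essentials and the expected rate from column-wise
permutations of the binary call matrix (default 1000, seeded); the
pan-cancer set repeats the selection over the genes × tissues membership
matrix. This follows the described objective, not any particular package's
internals; on fully permuted input the objective is flat noise, so the
selected set is unenriched for the reference rather than literally empty.
Tier 1 = genes found by both methods; tier 2 = by exactly one.

## Sample-size analysis

The overlap roster is repeatedly subsampled (50 replicates per size,
selection probabilities proportional to each line's lineage share, without
replacement; draws collapsing to one batch are redrawn), the batch model is
refitted on each subsample and applied to all screens, and each screen's
Pearson correlation against the full-overlap correction is recorded, along
with the no-correction baseline and the average silhouette width of overlap
screens under institute labels (near 0 = batch structure removed; distances
use all shared genes, mean-imputed). A single-lineage mode restricts the
roster before subsampling.

## The synthetic cohort

`simulate_dual_screens` emulates the two-institute design. Per-screen
scores are q_j·(base_g + effects_gl) + γ_ig + s·u_g·m_j + δ_ig·ε with:

- **Gene classes**: essentials base ~ N(−1, 0.15) (−1 being the
  conventional median of known common essentials after scaling),
  non-essentials N(0, 0.05) (a non-essential knockout has near-zero true
  fitness effect), 5% never-expressed genes.
- **Structure**: 16 lineages (Dirichlet-proportioned), 2 subtypes per
  lineage, 3 lineage-marker and 2 subtype-marker genes (−0.8); a sparse
  selective-dependency layer (20% of genes, each depleted by −0.4 to −1.2
  in 2–25% of lines) that gives every cell line a private dependency
  fingerprint — without it, matched counterparts are not identifiable
  within a subtype and identity recall is uninformative; optional
  co-essential pairs sharing a latent factor and biomarker specs
  (gene, CFE, tissue, Δ) whose carriers shift by −Δ·noise_sd (Cohen's-delta
  scale).
- **Batch effects**: per-gene location shift (sd 0.3 per batch) and noise
  scale (log-sd 0.1), both made mean-zero across the two batches: the
  common-mode component of independent draws is unidentifiable by any
  correction method — a gene shifted the same way at both institutes is
  indistinguishable from biology — so it belongs to the consensus signal,
  not the batch effect. A rank-1 component s·u_g·m_j (s = 0.3, m_j ~
  N(±0.5, 0.3) by institute) adds batch structure that is *not* per-gene
  location/scale, giving PC removal a distinct target.
- **Screen quality**: multiplicative phenotype-intensity factor
  q_j ~ N(1, 0.1) (clipped at 0.2), the target of the spline adjustment.
- **Noise**: iid N(0, 0.2). Overlap lines are screened once per institute
  with independent noise. All draws flow from one seed; each public
  operation derives its stream from (seed, stage).

Expression (log2(TPM+1)) gives never-expressed genes values < 0.01
everywhere; other genes draw an expressed fraction from U(0.6, 1), values
N(μ_g, 1) with μ_g ~ U(2, 8) when on and low-but-detectable trace
expression U(0.01, 0.5) when off, keeping the never-expressed class cleanly
separable as it is in bulk RNA-seq. The CFE matrix marks exactly the
planted carrier lines plus random background features; planted selective
genes double as oncogene gain-of-function annotations.

What the generator does **not** emulate: copy-number artifacts and
guide-efficacy heterogeneity (assumed handled by upstream pre-processors
whose gene-level outputs are this package's inputs), missing-data patterns
of real portals (the mask machinery is exercised synthetically), gene-gene
correlation beyond the planted factors, and the heavy-tailed score
distributions of real screens. Passing tests therefore demonstrate
correctness of the algorithms under the stated generative model, not
end-to-end performance on portal data.

## Problem sizes and numerical choices

Default test/analysis scale is 1000 genes and 200 + 250 screens with 168
overlapping lines — the overlap and lineage count of the motivating design
with a reduced gene space, chosen so the full suite runs in minutes while
keeping ≥100 observations behind every moment estimate. Tolerances: batch
equalization 1e-8 (means) / 1e-6 (variances) with shrinkage off; EB
iteration 1e-4 relative; spline idempotence 1e-6 on noiseless input; EM
tolerance 1e-6 with an sd floor of 0.5 rank units against component
collapse; correlation ties broken lexicographically by screen id.
Degenerate inputs (zero-variance genes, singleton subtypes, screens without
counterparts, empty mean bins) are excluded and logged rather than fatal,
except where a result would be meaningless (single batch, degenerate NNMD
null, no shared genes).

## Known limitations

The ADaM objective is implemented at the described level (TPR minus
permutation-expected rate) and may differ from specific package releases.
The skew-t optimizer can settle in local optima for near-degenerate
profiles; the fixed-df ladder and normal-limit candidate bound the damage
(NormLRT never goes materially negative) but extreme profiles may be
under-scored. The divergence threshold for duplicate resolution is computed
per dataset; consensual multi-dataset NNMD is supported by passing a
precomputed quality series. Nonparametric-EB correction and >2-batch
hierarchical designs are out of scope (additional batch labels are accepted
but treated flatly).
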