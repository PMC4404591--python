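# Methods

## Model and estimators

Per gene, normalized expression is decomposed by a model-II nested
hierarchical ANOVA, y_ijk = μ + x + z + A_i + B_ij + e_ijk, with
replicates (k) nested in individuals (j) nested in groups (i). Technical
covariates — mapped reads x and RIN z, standardized to mean 0 / sd 1 — are
removed first by sequential least squares (Type I order: intercept, x, z),
implemented as projection onto progressively orthogonalized design blocks.
On the residuals the nested sums of squares are computed from group,
individual, and grand means; the identity SS_A + SS_B + SS_e = total
centered SS holds for any data and is enforced in tests against a
brute-force mean-based oracle at 1e-10.

Degrees of freedom are a−1 (groups), b−a (individuals), and
N − b − (#covariates) for the error stratum, the covariates being
library-level terms that consume replicate-level information. Variance
components come from the expected mean squares

    E[MS_e] = σ²,  E[MS_B] = σ² + n₀ σ²_B,  E[MS_A] = σ² + n₀′ σ²_B + n_b σ²_A,

with the standard unbalanced-nested coefficients

    n₀  = (N − Σ_i (Σ_j n_ij²)/n_i) / (b − a)
    n₀′ = (Σ_i (Σ_j n_ij²)/n_i − Σ_ij n_ij²/N) / (a − 1)
    n_b = (N − Σ_i n_i²/N) / (a − 1)

(n₀ = n₀′ = replicates, n_b = libraries per group when balanced). Negative
component estimates are truncated at zero after plug-in, which is why the
variance-based Mst/Mit/Met can be exactly 0 while the SS-based Nst/Nit/Net
are strictly positive whenever total SS is. Genes with (numerically) zero
total SS are flagged `defined = False` and excluded from gene-level
statistics rather than propagating NaNs silently.

### A caution on regress-then-decompose

Removing library-level covariates globally before the nested decomposition
mixes strata: projecting out a direction that is random with respect to the
design removes, from each stratum, variance proportional to that stratum's
*share of the removed direction*, which for heteroscedastic strata is not
proportional to its degrees of freedom. In simulation this inflates MS_e by
several percent and deflates MS_B even when the covariates carry no real
effect. The parameter-recovery validation therefore runs the estimator
under its own model (no covariate terms, none simulated); analyses of real
designs keep the covariates, accepting this small, structural bias as the
price of technical-artifact removal.

### Differential expression among individuals

Three per-gene tests: the F-ratio MS_B/MS_e on (b−a, df_e); the inverted
ratio MS_e/MS_B for excess intra-individual variation; and a Gaussian
likelihood-ratio comparison of covariates-only vs covariates+individual,
N·ln(RSS₀/RSS₁) on b−1 df against chi-squared. Gaussian likelihoods are
justified by the near-equivalence of normal and negative-binomial fits on
variance-stabilized counts. All p-values are Benjamini–Hochberg adjusted
per statistic across genes.

### Full trait model

The 13-factor partially nested model (no interactions) adds, in fixed
order, sex, birth weight, birth length, delivery manner, maternal age,
maternal BMI, alcohol, and vegetarian diet between the technical covariates
and the group/individual factors. Sequential SS are computed by block-wise
orthogonalization, so each factor's df is its *additional* rank — the
individual block, nested above eight individual-level traits, loses their
df automatically; constant factors are dropped with a warning and zero SS.
η² = SS/SS_T per factor sums to 1 with the error stratum included. Effect
direction for single-df traits is the sign of the orthogonalized
coefficient oriented along increasing trait values.

## Permutation and resampling nulls

* **individuals among groups** (Nst null): whole individuals, replicates
  attached, are reassigned to groups preserving group sizes; per
  permutation a random gene subset (default 100 genes × 1,000 permutations)
  is refitted and pooled. Cutoff = 99th empirical percentile (linear
  interpolation).
* **replicates among individuals within groups** (Nig null, and the mean
  Nit p-value): library→individual assignments are shuffled within each
  group, randomizing inter-individual differences while leaving group means
  — and hence each gene's SS_A — invariant. If the data are invariant under
  the shuffle (within-group-constant libraries) the null is flagged
  degenerate.
* **reads among replicates** (mean Net p-value): each individual's per-gene
  read total is redistributed among its replicate libraries multinomially
  in proportion to library depth (implemented by conditional binomials),
  conserving individual totals and expected library depths; the permuted
  counts are renormalized before refitting. This operationalizes an
  otherwise under-specified resampling of reads.
* **artificial genes** (stabilizing/diversifying null): on the
  individual-level matrix (replicate counts summed, independently
  renormalized), every gene is shifted additively to the global mean; each
  of 10,000 artificial genes draws, per individual, the centered value of
  one uniformly chosen real gene, and its variance is taken across all
  individuals ignoring groups. Cutoffs at the 1st and 99th percentiles.

Mean-level apportionment p-values use the add-one convention
(1 + exceedances)/(n_perm + 1). Permutation streams are seeded
independently per scheme from a master seed.

## Selection-profile classification

Directional: gene Nst above the Nst-null cutoff. Balancing: Nig above the
Nig-null cutoff. Stabilizing/diversifying: inter-individual variance below
the 1st / above the 99th artificial-gene percentile (mutually exclusive by
construction; overlaps with directional are allowed and expected). Neutral
is the complement of the union. These are profile classifications, not
formal tests of selection.

Two calibration facts quantified by the test suite rather than assumed:

* Under a scheme's own null (σ²_A = 0 for the group scheme, σ²_B = 0 for
  the individual scheme, homogeneous components for the variance scheme)
  each one-sided rule flags ≈1% of genes.
* The balancing rule has an intrinsic power ceiling under contamination.
  Because the within-group shuffle preserves SS_A, a balancing gene's
  permuted Nig differs from its observed Nig only through MS_B shrinkage
  (a factor ≤ 2 at two replicates); when balancing genes exceed ~1% of the
  null pool, the 99th-percentile cutoff lands inside their own permuted
  distribution and sensitivity saturates near 0.5–0.75 regardless of
  effect size. This is a property of the pooled-null design itself.

## Synthetic data generator

Latent log2 expression per gene: baseline ~ Uniform(range) plus Normal
group/individual/replicate effects with variances (σ²_A, σ²_B, σ²), plus
small technical terms (coefficients × standardized log library size and
RIN). Counts are negative binomial (gamma–Poisson) with mean proportional
to 2^latent × library size and dispersion a + b/mean. The latent matrix is
retained as the model's y for estimator validation independent of counting
noise.

Defaults (chosen once as the study conditions; all configurable):

| parameter | default | rationale |
| --- | --- | --- |
| design | 4 groups × 10 individuals × 2 replicates | the replicated multi-group placenta design |
| (σ²_A, σ²_B, σ²) | (0.02, 0.15, 0.08) log2² | implies apportionment proportions (0.08, 0.60, 0.32) |
| baseline range | (0, 12) log2 units | wide bulk dynamic range |
| library size | 1.2–1.7 × 10⁶ reads | per-library mapped-read scale |
| RIN | 7–10 | typical intact-RNA range |
| technical coefficients | 0.07 log2/sd each | ≈2% of variance per covariate |
| dispersion | 0.01 + 0.5/mean | BCV² ≈ 0.01 at depth, extra Poisson-scale noise at low counts |
| σ²_e-vs-mean slope | 0 (optional) | see below |

Selection regimes claim disjoint gene blocks chosen deterministically from
the seed: directional adds per-group mean shifts (default +2 log2 on one
group; optionally a per-gene random ordering of the shift vector, since a
shared pattern is invisible to correlation distances); balancing inflates
σ²_B (×5), pins σ²_A = 0 *and centers the realized individual effects
within each group* — individual diversity otherwise propagates into
group-mean scatter in exactly the way the permutation null reproduces, so
only realized-mean pinning (the biology of a shared optimum) produces a
detectable balancing profile; stabilizing shrinks σ²_B and σ² (×0.1);
diversifying inflates σ²_B (×5).

What the generator does not emulate: cell-type composition (replicate-level
σ² is the stand-in for intra-tissue heterogeneity), isoforms, mapping
artifacts, batch structure beyond the two covariates, and
variance-stabilization-resistant mean–variance trends. On the shifted-log
scale, NB counting noise contributes ≈(1/ln2)²(1/μ + a + b/μ) and so
*decreases* with expression level; the positive correlation between mean
expression and residual SS seen in real tissue reflects replicate
variability growing with expression, which the generator reproduces only
through the optional `sigma2_e_mean_slope` coupling on a well-covered gene
set. Passing tests therefore validate the estimators and the resampling
machinery, not the realism of low-count noise behavior.

## Normalization and QC

Size factors are median-of-ratios against the per-gene geometric mean
(genes expressed in all libraries; optional pseudo-reference fallback);
expression is log2(count/factor + 1). The method and pseudocount are
recorded in the matrix provenance. Exact reproduction of model-based
variance-stabilizing transforms is out of scope; the shifted log is
deterministic, monotone, and dependency-free.

Replicate QC clusters libraries by average linkage on 1 − |r| (Pearson
across genes; constant libraries get distance 1 with a warning). An
individual passes when its replicate libraries form an exclusive subtree
(a cherry for two replicates); failures are listed for removal and the
filter is idempotent. QC runs on pre-covariate-adjustment normalized
values. Individual-level analyses (PCA, variance nulls, k-means, trees)
sum replicate counts per individual and renormalize independently.

## Structure analyses

PCA centers genes and decomposes by SVD with a deterministic sign
convention (largest-magnitude loading positive). PC–trait screening uses
Pearson correlations with Bonferroni adjustment over the full PC × trait
grid. Population distance trees are UPGMA on weighted mean pairwise
apportionment statistics; the weighting (default per-gene total SS of the
pairwise fit, alternatives: uniform, mean expression) is recorded in the
output, and group order is lexicographic, which also fixes agglomeration
ties. Pairwise apportionments refit covariates within each group pair.
k-means profile partitioning standardizes each gene to mean 0 / sd 1
across individuals and uses 10 restarts at a fixed seed.

## Numerical choices and degenerate inputs

Percentile cutoffs are empirical order statistics with linear
interpolation. QR-based block orthogonalization drops columns collinear
with earlier blocks at tolerance 1e-9 × scale. Zero-variance genes,
constant traits, constant libraries, empty permutation nulls, and
single-individual groups are each either flagged or rejected with a named
error, as listed per module. Validation experiment sizes (2,000-gene
recovery, 1,000 × 100 and 200 × 50 permutation runs, 2,200-gene confusion
matrix) were chosen to make Monte-Carlo error small relative to the effect
bands being checked while keeping each experiment in the seconds range.

## Known limitations

* Per-gene ratio statistics are noisy at 3 group df; means across genes of
  M statistics carry a small Jensen-type bias that shrinks with group
  count, not gene count.
* The covariate-projection stratum mixing described above biases MS_e
  upward by a few percent in covariate-free data.
* The balancing rule's power ceiling under contaminated pooled nulls
  (above).
* REML/shrinkage estimation, interaction terms, model-based DE, enrichment
  analysis, and co-expression networks are out of scope.
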