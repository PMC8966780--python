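# Methods

`omibone` implements an integration analysis for paired gut-microbiome and
serum-metabolome profiles measured on the same subjects together with a
quantitative phenotype (a standardized bone-mineral-density measurement in
the motivating setting). This note records the models, the numerical
choices, and what the synthetic test bed does and does not establish.

## Compositional preprocessing

Shotgun taxon profiles carry only relative information, so all microbiome
analyses start from proportions. Rare taxa with mean relative abundance
below 10⁻⁴ (0.01%) are removed before any transform; rows are *not*
re-closed afterwards by default, because the centred log-ratio (CLR)
transform is scale-invariant and the choice is then immaterial — the only
consumer that is sensitive to closure, the Bray-Curtis distance, receives
re-closed rows. CLR maps each composition to
log(x_j + δ) − mean_j log(x_j + δ), a zero-sum vector. Zeros are offset by
δ = half the smallest nonzero relative abundance (a multiplicative-
replacement-style choice; configurable). Gene tables are normalised to
transcripts per million, G_k = (r_k/L_k)/Σ_i(r_i/L_i)·10⁶.

## LC-MS feature-table QC

The serum pipeline runs in a fixed order: detection filter (features must
appear in ≥50% of pooled-QC injections and ≥80% of biological samples) →
k-nearest-neighbour imputation (k = 10, Euclidean distance on log
intensities over shared features; k is not dictated by any convention we
know of, 10 is a common default) → probabilistic quotient normalisation
with the feature-wise median over QC samples as the reference spectrum
(the QC pool is the designed reference; median over all samples is the
fallback) → QC repeatability filter (relative standard deviation over QC
samples ≤30%) → log transform and autoscaling with the n−1 variance
denominator. Missing values are NaN throughout, never zero. Batch
correction is reduced to an optional per-batch median-centering hook:
spline-based injection-order correction needs acquisition metadata the
package does not model.

## Zero-sum elastic net (log-contrast screen)

Taxon effects on the phenotype are screened with

  minimise ‖y − β₀ − Xβ‖² + λ₁‖β‖₁ + λ₂‖β‖₂²  subject to Σβ = 0,

on CLR covariates. The zero-sum constraint makes the fit invariant to the
arbitrary compositional scale. The ridge term is squared, the standard
elastic-net convention. The solver is a cyclic two-coordinate descent:
each move perturbs a pair (β_j, β_k) by (+δ, −δ), so the constraint holds
exactly at every iterate; δ has a closed piecewise-quadratic form (four
sign regions plus two breakpoints). For each cycled coordinate the best
partner is chosen, so a converged sweep certifies that no pair move
improves the objective beyond tolerance (10⁻⁸ relative). The kernel is
JIT-compiled with numba, with an equivalent numpy fallback. λ is tuned on
a 50-point log-spaced path (λ_max = range of Xᵀy over the mixing ratio,
down four decades... ratio 10⁻³) by 10-fold cross-validated MSE with the
one-standard-error rule; the mixing ratio defaults to 0.5.

The second stage tests every taxon by partial Spearman correlation —
Pearson correlation of rank-transformed x and y residualised on
rank-transformed covariates, p-values from the t approximation on
n − n_cov − 2 degrees of freedom. The final call is
`stage-1 selected AND BH-FDR < 0.05`. The Benjamini-Hochberg correction
is computed **table-wide** (over all tested taxa) by default: stage 1
selects on the same data stage 2 tests, so restricting the multiplicity
set to the selected subset understates the number of comparisons actually
performed — on planted-truth cohorts the subset-scoped rule yields an
empirical false-discovery proportion of ≈0.22 at nominal 0.05, while the
table-wide rule controls it (≈0.04) at unchanged sensitivity. The
subset-scoped FDR is still computed into the `fdr_subset` column, and
`fdr_scope="selected"` restores it as the deciding value, since that is
the convention screened-subset association tables are usually reported
under.

## PLS-VIP metabolite screen

Partial least squares (NIPALS via scikit-learn, no rescaling — inputs are
already autoscaled) regresses the phenotype on the metabolite matrix; the
component count is chosen by 5-fold cross-validated Q² with a cap of 5.
Variable importance in projection is

  VIP_j = sqrt( p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a ),

where SS_a is the phenotype variance explained by component a; squared
VIPs average to one, so VIP ≥ 2.0 flags features contributing at least
four times the average. Each metabolite is also tested individually by
OLS adjusted for the covariates.

## Fecal-metabolite imputation

Per-metabolite elastic-net models (scikit-learn `ElasticNetCV`, L1 ratio
0.9) map microbial gene abundances to fecal metabolite levels using a
paired reference set; imputation is the linear map Ŷ = G·W + b. A
metabolite is retained when its training-set Spearman ρ between observed
and predicted values exceeds 0.3. The ρ used for this rule is computed on
**out-of-fold** predictions within the reference set: with many more
genes than reference samples the in-sample fit is optimistic enough to
retain a quarter of pure-noise metabolites, whereas out-of-fold retention
of pure noise is below 1%.

## SparCC co-occurrence network

Correlations computed directly on proportions carry a negative closure
bias. SparCC estimates basis correlations from log-ratio variances
T_ij = var(log x_i/x_j): under a sparsity assumption the basis variances
ω solve a linear system with diagonal p−1 and off-diagonal 1, and
cov_ij = (ω_i + ω_j − T_ij)/2. The most-correlated pair above |ρ| = 0.1
is excluded from the system and the solve repeated (20 rounds); the
estimate is averaged over 10 Dirichlet(counts+1) resamples of each
sample's composition. Two-sided permutation p-values shuffle every taxon
column independently; p = (1+#{|ρ_perm| ≥ |ρ_obs|})/(1+B). Edges require
|ρ| > 0.5 and p < 0.001 (both strict). Because the smallest attainable p
is 1/(B+1), the pipeline uses B = 1999 — at B ≤ 999 the p criterion is
unsatisfiable — with a single Dirichlet draw per permutation run; the
noisier permutation estimates widen the null, which errs conservative.

## Coinertia and the RV coefficient

Global microbiome–metabolome concordance: PCoA of Bray-Curtis distances
(re-closed abundances) and PCA of the metabolite matrix feed a coinertia
analysis on the leading axes covering ≥80% of positive inertia, capped at
10 axes (the cap keeps the statistic from being dominated by noise axes).
Total coinertia is Σ_jk cov(X_j, Y_k)² with uniform row weights 1/n, and

  RV = coinertia(X,Y) / √(coinertia(X,X)·coinertia(Y,Y)) ∈ [0, 1].

Significance is a Monte-Carlo permutation test (default 999 permutations)
that permutes the rows of one table.

## Supervised sparse CCA

The integrative feature selection maximises uᵀXᵀYv subject to ‖u‖₂ ≤ 1,
‖v‖₂ ≤ 1, ‖u‖₁ ≤ c₁, ‖v‖₁ ≤ c₂, and u_j = 0 outside Q₁, v_j = 0 outside
Q₂, where Q₁/Q₂ are the 50 features per modality with the largest
univariate phenotype correlation (an α-threshold option exists). The
alternating update soft-thresholds XᵀYv (restricted to the support) and
renormalises, with the threshold found by bisection so the L1 bound
holds; the objective is non-decreasing by construction and asserted so.
The canonical pair is oriented so cor(Xu, y) ≥ 0. (c₁, c₂) are tuned on a
6×6 log-spaced grid over [1, √|Q|] by 10-fold cross-validated held-out
canonical correlation with a one-standard-error sparsity rule — the
held-out-correlation surface is flat towards dense models, and without
the rule the tuned support absorbs noise features. Only the first
canonical dimension is estimated. Loadings are the correlations of each
selected feature with its own modality's canonical score.

## Inter-omics Gaussian graphical model

Nodes are the sCCA-selected features plus the phenotype; the correlation
matrix is used throughout, making the analysis invariant to column
scaling. A graphical-lasso path (100 log-spaced penalties from the
empty-graph threshold down two decades) proposes up to 100 distinct edge
structures; each is refit without regularization by iterative
proportional scaling over the maximal cliques of the structure (works for
non-decomposable graphs; tolerance 10⁻⁸, 1000 cycles), which matches the
sample covariance exactly on the diagonal and the edge set while zeroing
the precision off the structure. The selected model minimises

  EBIC = −2ℓ + |E| log n + 4γ|E| log p,  γ = 0.5

(the usual high-dimensional default; γ = 0 recovers BIC), with ties going
to the sparser structure. Edges carry partial correlations
r_ij = −Ω_ij/√(Ω_ii Ω_jj); reported statistics are the edge density
|E|/(p(p−1)/2) and the transitivity (closed-triple fraction, undefined
below three nodes).

## Synthetic cohorts

The generator emulates the target study's data shapes — by default 500
subjects, 600 taxa (essentially all above the 0.01% filter), 400
metabolite features with one pooled-QC injection per ten samples, six
covariates, and a standardized quantitative phenotype:

* **Compositions** are softmax of a Gaussian with a power-law mean
  profile (heavy-tailed abundances, a few dominant taxa) plus sparse
  background co-occurrence factors: ~40% of taxa load on one of five
  shared factors with strength varying in [0.2, 0.6]. Counts are
  multinomial at a fixed depth of 10⁵ reads.
* **The phenotype** is an exact additive sum — recorded component by
  component — of a covariate term with the empirical sign pattern
  (BMI and exercise positive; years since menopause and FSH negative;
  estradiol positive; age ≈ 0), a zero-sum taxon term CLR·β with ±0.8
  effects on an even number of planted taxa, a metabolite term on
  standardized log intensities, and Gaussian noise (sd 1).
* **Cross-omics blocks** share a latent factor between member taxa (log
  abundance) and member metabolites (log intensity) at correlation
  `block_rho` (default 0.6). Loading signs follow the members' planted
  effect signs: with uniform signs the zero-sum ± effects cancel the
  factor out of the phenotype and no phenotype-supervised method can see
  the block. Blocks are planted on phenotype-associated features first,
  so supervision and cross-covariance point at the same target.
* **Identifiability choice.** Planted-effect taxa are kept out of the
  background co-occurrence factors. Otherwise correlated-but-non-causal
  neighbours of planted taxa are irreducible false positives of *any*
  marginal screen and "false discovery" loses its meaning against the
  planted labels. Consequently the recovery benchmarks certify the
  screens under marginal identifiability — they do not measure
  performance under heavy causal/co-occurring confounding, which real
  gut communities certainly contain.
* **Metabolites** are log-normal (log-sd 0.5 around per-feature means),
  with a single linear injection-order drift term (amplitude 0.1 on the
  log scale) and intensity-dependent missingness: the masking probability
  is a logistic function of log intensity calibrated by bisection so the
  overall rate hits the configured value (default 10%). QC rows are the
  exponential of the mean log intensity plus small technical noise
  (sd 0.05).

What passing the synthetic benchmarks does **not** show: robustness to
real taxonomic mis-assignment, to non-lognormal intensity distributions,
to structured batch effects beyond a single drift term, to nonlinear
microbe–metabolite relationships, or to confounding between planted and
background structure (excluded by design, above).

## Problem sizes in the test suite

The recovery benchmarks run 20 replicate cohorts of 500 subjects with 200
taxa (10 planted zero-sum effects of ±0.8), the sCCA benchmark 20 cohorts
with one 10-taxon/5-metabolite block at ρ = 0.6, and the GGM benchmark 20
draws of n = 2000 from 10-node sparse precisions; permutation-test
calibration uses 500 null replicates at B = 499. These sizes were chosen
so each benchmark estimates its rate with usefully small Monte-Carlo
error while the whole suite stays comfortably runnable on a laptop core.

## Known limitations

* One canonical dimension only; linear relationships only.
* The SparCC permutation null uses independent column shuffles, which
  destroys the compositional coupling along with the dependence; this is
  the standard scheme but slightly misstates the null for very uneven
  compositions.
* The GGM refit assumes a positive-definite sample correlation matrix;
  with more nodes than samples the path still runs but the unregularized
  refits of dense structures fail and those structures are skipped.
* The imputer's elastic-net models assume the reference and target
  cohorts share the gene-metabolite map; no transfer correction is
  attempted.
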