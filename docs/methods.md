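# Methods

This note records the statistical models `clonegs` implements, the
numerical choices behind them, what the bundled simulator does and does not
emulate, and the design decisions that were genuinely open.

## Data model

Genotypes are biallelic SNP dosages in {0, 1, 2} with missing values; the
package treats octoploid array calls as disomic dosages throughout, because
that is the resolution at which SNP arrays for polyploid crops deliver
calls and the resolution every downstream method consumes. Phenotypes are
plot-level records from clonally replicated randomized-complete-block
trials with beds nested in replicates and subplots nested in beds;
genotypes are nested in full-sib families.

## Marker quality control

Markers are removed when MAF < `maf_min` (default 0.05) or missing rate
> `miss_max` (default 0.05); markers exactly at a threshold are kept
(elimination is strict by convention; both thresholds are parameters, so
the opposite convention is one call away). Allele frequencies use
non-missing calls only — the only defensible choice when missingness
exists. Imputation replaces a missing call with the expected dosage 2p
(real-valued, not rounded; a `round_to_int` flag exists). Imputing at the
mean is exactly mean-preserving per marker.

## Relationship matrices

* **Pedigree A** — tabular method; founders are non-inbred and unknown
  parents act as unique unrelated founders.
* **Genomic A_g** — the allele-frequency-weighted estimator with marker-
  specific standardization 2p(1−p) and the adjusted diagonal
  1 + [x² − (1+2p)x + 2p²]/2p(1−p). With missing calls, each pair of
  individuals averages over the markers observed in both (complete-case;
  no imputation), matching how such matrices are built for GBLUP from raw
  panels; `complete_case=False` uses an imputed panel for speed. Because
  frequencies are estimated from the sample, the off-diagonal mean of an
  unrelated panel is −1/(n−1), not 0 — tests account for this.
* **Bending** — non-PSD matrices are repaired by eigenvalue clipping:
  eigenvalues below `eps` (default 1e−6) are raised to `eps` and the matrix
  reconstructed. Clipping is deterministic, idempotent and recorded in the
  matrix metadata. Every solve is preceded by bending; inverses are never
  formed explicitly unless requested.

## REML engine

All mixed models reduce to a marginal covariance linear in the parameters,
V(θ) = Σⱼ θⱼ Mⱼ with Mⱼ = Zⱼ Gⱼ Zⱼ′ (heterogeneous residuals enter as
diagonal indicator blocks). The residual log-likelihood uses the
basis-invariant form (with the log|X′X| normalization), so reference-level
and sum-to-zero fixed-effect codings give identical criteria. Updates are
average-information Newton steps with step-halving; when no damped AI step
increases the likelihood, an EM step (θⱼ ← θⱼ + θⱼ²/qⱼ·[y′PMⱼPy − tr(PMⱼ)])
is taken. Convergence requires relative log-likelihood change < 1e−8 and
relative parameter change < 1e−6. Components are kept above
1e−8 × var(y) by projection; components that finish at the floor are
reported as 0 with a boundary flag and excluded from the information matrix
used for standard errors. Rank-deficient fixed-effect blocks are pruned by
pivoted QR and the dropped columns reported. Dense n×n factorizations are
used throughout — the intended scale is hundreds to a few thousand plots
per fit.

On balanced one-way designs the engine reproduces closed-form ANOVA
estimators to ~1e−8, which the tests assert.

## Trial models and genetic parameters

* **Single-trial model**: fixed intercept + replicate (+ transplant-weight
  covariate when a Wald test at 5% keeps it — the covariate applies to
  seedling-stage trials where transplants are weighed); random
  bed-within-replicate, subplot, additive genotype (covariance A or A_g),
  family, clone-within-family, residual. Heritabilities: h² = σ²ₐ/σ²ₜ and
  H² = (σ²ₐ+σ²f+σ²c)/σ²ₜ with σ²ₜ the sum of all six components; the
  ad-hoc clonal-mean heritability divides the residual by the harmonic
  mean number of replicates per genotype. The typeset definition of that
  denominator is ambiguous about which terms are divided by r; the literal
  reading (only σ²ₑ/r) is the default and a `clone_mean` mode divides bed,
  plot and residual all by r. The mode is stamped on every report.
  Standard errors of all ratios are delta-method from the AI covariance
  (the source tables print SEs without stating a method; delta is the
  standard choice).
* **Paired-trial model**: trial and replicate-within-trial fixed;
  bed, subplot and residual variances heterogeneous per trial; additive
  effect with relationship structure plus an additive-by-trial deviation.
  As typeset, an identity-covariance genotype-by-trial additive deviation
  would be exactly aliased with the identity clone-by-trial term, so the
  additive-by-trial deviation here carries the same relationship structure
  as the main additive term, block-diagonal within trial — the classical
  Type-B construction, which restores identifiability. Type-B
  r_B = σ²ₐ/(σ²ₐ+σ²ₜₐ) with a delta-method SE; when the interaction
  component is pinned at zero, r_B = 1 exactly.
* **Adjusted means**: genotype (total clonal value) fixed; replicate, bed
  and subplot random (a flag moves replicate to fixed); the per-genotype
  GLS mean at the average covariate level is the response passed to all
  whole-genome regressions. Genotypes aliased with design strata are
  reported as inestimable.

## Whole-genome regression

All four Bayesian models share y = 1μ + Xβ + e on dosages centered by 2p
(optional 2p(1−p) scaling is off by default) and a scaled-inverse-χ²
residual variance; they differ in the effect prior: BRR (common Gaussian
variance), BL (Park–Casella double-exponential via per-marker exponential
mixing variances and a Gamma(1.1, ·) hyperprior on λ²), Bayes B (spike +
per-marker scaled-inverse-χ² variances, i.e. a scaled-t slab) and Bayes C
(spike + common Gaussian slab). The slab conventions follow the reference
software for these samplers; a `swap_slabs` switch exchanges the Bayes B/C
conventions for sensitivity analysis. Prior scales follow the usual
R²-partition rule (default R² = 0.5): prior modes split var(y) between
genetic and residual parts, with the genetic mode divided by the prior
inclusion probability π (default 0.5, Beta-updated with prior weight 10)
for the mixture models. Chain defaults are 12 000 iterations, 2 000
burn-in, thinning 5 — desk scale; an effective sample size of the residual
variance below 100 triggers a warning, not a failure. Chains are
bit-reproducible for a fixed seed (single compiled sampler, own RNG
stream). With variances held fixed, the BRR posterior mean equals the
closed-form ridge solution — the primary sampler oracle.

GEBVs for new individuals are Σᵢ (xᵢⱼ − 2pᵢ,train)·β̂ᵢ, reusing training
centering constants; the intercept is omitted because every reported
metric is translation-invariant.

## Kernel methods

GBLUP, PBLUP and RKHS all fit y = 1μ + Za + e with a ~ N(0, σ²ₐK) where K
is A_g, A, or the Gaussian kernel K = exp(−h·d²/mean(d²)) on squared
Euclidean marker distances. Distances are normalized by the mean
off-diagonal d², which makes the bandwidth unit-free; h defaults to 0.5 on
that scale and is recorded in metadata (the normalization constant and
default bandwidth are package choices — sensitivity to h should be
reported rather than assumed). Unphenotyped individuals are carried in K
and predicted jointly through their kernel covariances with the training
set; this is precisely how marker-only (incomplete-information) prediction
works for the kernel methods. Multi-kernel averaging and Bayesian
bandwidth sampling are out of scope.

## Validation and selection efficiency

Cross-validation partitions genotypes into k folds (default 5; sizes
differ by at most one; deterministic under seed), trains on k−1 folds,
and pools out-of-fold predictions into a single PA (per-fold correlations
are also emitted; pooled is primary). True validation trains on one
trial's adjusted means and scores marker-only predictions against another
trial's adjusted means; its PACC uses the test trial's clonal-mean
heritability by default (a flag selects the training trial's).
PACC = PA/√h²c̄ — the rescaling under which PACC estimates
corr(a, â), since corr(y_adj, a) ≈ √h²c̄; the literal PA/h²c̄ reading is
available behind a flag and values above 1 are flagged rather than
clipped.

Selection efficiency compares top-5%/10% sets ranked by marker-only
predictions against sets ranked by a complete-information GBLUP fit on the
validation trial itself: gain(S) = mean complete-information GEBV of S
minus the candidate-population mean, efficiency = 100·gain(S_inc)/
gain(S_comp). Measuring gain as deviation from the population mean makes
100% attainable, 0 the random-selection expectation, and caps efficiency
at 100% by construction. Ties break by stable id order.

## Linkage disequilibrium

r² is the squared Pearson correlation of dosage vectors (composite LD; no
phasing) over all within-LG pairs. The relatedness-corrected rv²
GLS-centers each dosage vector under a relationship matrix V (subtracting
the generalized mean) and whitens by the Cholesky factor of V before
correlating; with V ∝ I the corrected statistic equals r² exactly. V
defaults to the GRM built from the markers of the same linkage group. An
LG-specific GRM estimated from tens-to-hundreds of markers is rank
deficient or ill-conditioned, and whitening through near-null eigenvalues
amplifies noise catastrophically, so eigenvalues are floored at 0.05 on
the unit-diagonal scale of the GRM before factorization; this
regularization is the package's choice and is recorded here and in the
matrix metadata. Decay profiles bin pairs at 1 cM by default and report
per-bin means and pair counts; empty bins are kept and flagged.

## The simulator

The generator emulates the study conditions the analysis stack assumes:

* **Founder LD** — each founder haplotype is a mosaic over a small pool of
  ancestral haplotypes (default 4 per linkage group), switching as an
  exponential process with scale `block_cm` (default 10 cM). This yields
  r² ≈ 0.25–0.3 between tightly linked markers decaying smoothly toward
  the background over ~15 cM — the qualitative pattern of a closed
  breeding population with long-range LD. `block_cm = 0` gives linkage
  equilibrium.
* **Population structure** — a circular mating design over the parents
  (n parents → n full-sib families, default 22 × 10 progeny), with
  Mendelian gene drop under Haldane recombination
  (c = ½(1 − e^(−2d/100))). Allele frequencies are conserved in
  expectation and full sibs average a genomic relationship of 0.5, both
  asserted by tests.
* **Trait architecture** — a configurable number of genotyped QTL (default
  100 small effects; the motivating traits show no large-effect QTL).
  Additive values are rescaled to hit the target variance exactly, so the
  simulated h² is the true simuland, not a random draw. Non-additive
  variance enters as family and clone-within-family deviations — exactly
  the partition the single-trial model estimates — rather than as explicit
  dominance at loci. Total phenotypic variance is 1 by construction;
  defaults put heritability targets in the 0.03–0.46 narrow-sense range
  of the motivating traits.
* **Field design** — default 3 replicates × 3 beds × 8 subplots with
  bed/subplot variance fractions of 0.05 each; an optional per-plant
  transplant-weight covariate with configurable effect.
* **Paired trials** — trial-specific additive values
  a_t = √r_B·a₀ + √(1−r_B)·d_t with marker-based trial-specific
  deviations, so the cross-trial additive correlation equals the Type-B
  target. Paired trials share a configurable fraction of genotypes
  (default 15%, emulating common checks); the remainder split between
  trials and connect only through relatedness — without this split,
  "true" validation would be in-sample and trivially easy.

What the simulator does **not** emulate: octoploid meiosis (markers are
diploid dosages end to end), selection across generations, epistasis or
explicit dominance, spatial field trend beyond the bed/subplot strata, and
genotyping error. Passing recovery tests therefore demonstrates correct
inference under the assumed model at realistic sizes, not robustness to
model misspecification in real field data.

## Scaled-down study sizes

Tests and the acceptance script run simulations of 110–220 genotypes with
240–600 markers and 3 clonal replicates, with Gibbs chains of 6 000–12 000
iterations. These sizes are chosen so the whole suite runs on a single CPU
in about a minute while keeping standard errors small enough for 2-SE
recovery checks to be informative. Recovery studies use the genomic (not
pedigree) relationship matrix: in a two-generation pedigree the expected
relationships are block-constant within families and nearly aliased with
the family + clone terms, whereas realized genomic relationships vary
within families (Mendelian sampling) and identify the additive component —
the same reason deep-pedigree or genomic data are needed in practice.

## Known limitations

* Dense-matrix REML scales as O(n³) per iteration; fits beyond ~3 000
  plot records need a sparse or MME-based engine.
* No spatial (AR1×AR1) residual models; spatial trend is controlled only
  through design strata.
* No multi-trait models, no single-step blending of A and A_g, no
  haplotype-frequency (D′) LD, and no GWAS-style per-marker testing.
* The Wald test for the covariate is asymptotic (χ²₁); small-sample
  refinements (Kenward–Roger) are not implemented.
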