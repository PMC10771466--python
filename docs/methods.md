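# Methods

`cmqtl` implements a cell-morphological QTL (cmQTL) analysis: from
single-cell morphology feature tables and donor genotypes to donor-level
composite traits, variance decomposition, gene-level rare-variant burden
and per-variant common-variant association, permutation nulls, and an
effect-size-mixture projection of discovery power at larger sample sizes.
This note records the models, the defaults and why they were chosen, the
numerical choices, and what the synthetic-data tests do and do not show.

## The synthetic cohort

The generator emulates an iPSC Cell Painting cohort: each donor's cell line
is imaged on exactly one plate, in several wells, so plate and donor effects
are partially confounded exactly as in such a design. Defaults follow the
cohort shape this package models: 297 donors across 7 plates, 8 wells per
line, and an isolate-cell fraction of 2.52% (cells with zero neighbors);
counts that are impractical at full scale are desk-scaled by default
(40 traits, 500 common variants, 120 genes, mean 150 cells per well) and
fully configurable.

Each cell's trait value is

    y = plate + well-position + donor (+ genetic effect) + cell residual,

independent Gaussians scaled to the configured variance fractions (default
plate 0.60, well 0.05, donor 0.17, residual 0.18 — a plate-dominated profile
with a smaller donor-shared component, the regime these cohorts typically
show). Planted genetic effects are expressed on the cell-level trait scale
(total cell variance 1) and multiply the variant dosage or the gene carrier
indicator; they are registered in a `GroundTruth` object alongside
per-gene carrier lists.

Well-position effects are a property of the plate layout (row/column
position), shared across plates, matching the `(1|Well)` term of the
variance-component model. Donors are assigned *randomized* positions within
their plate. This matters: an earlier layout that placed donors at
consecutive positions by within-plate rank made donors at the same rank on
different plates share their entire well set, which correlated their
donor-level residuals and visibly inflated null association scans
(pooled λ ≈ 1.16); with randomized positions the overlap between any two
donors' well sets is negligible and pooled null λ returns to ≈ 1.0.

Genotypes are independent biallelic variants drawn from Hardy-Weinberg
proportions at allele frequencies uniform over the configured ranges
(common: 0.05–0.5; rare: 0.001–0.01). Rare variants are grouped into genes
with HIGH or MODERATE annotated impact. One caveat of desk-scale cohorts:
at n ≈ 100–150 donors a variant with three alternate alleles already
exceeds the MAF < 1% rare filter, so fixtures that need well-carried genes
use many ultra-rare variants per gene rather than a few borderline ones.
Optional planted QC-failure classes (low MAF, high missingness,
Hardy-Weinberg violation) exercise the genotype filters with exact
bookkeeping.

Randomness is one seed fanned into named substreams (genotypes, profiles,
missingness, metadata), so planting a phenotype effect cannot perturb the
genotype draw and identical configurations are byte-reproducible.

What the generator does **not** emulate: pixel-level image content and real
CellProfiler feature semantics (traits are abstract); linkage
disequilibrium beyond simple block-correlation fixtures; non-Gaussian trait
distributions; batch effects that interact with genotype. Passing tests
therefore demonstrate correctness of the statistical machinery under the
declared model, not robustness to every pathology of real imaging data.

## Profile processing

Cells missing more than 5% of traits are removed; blocklisted, structurally
absent, and (near-)zero-variance traits are dropped (variance tolerance
1e-12). Cells are split into colony (≥1 neighbor) and isolate (0 neighbors)
contexts, averaged per well (missing values ignored), and each trait is
gaussianized by rank-based inverse normal transformation across all plates
jointly: Φ⁻¹((rank − c)/(n − 2c + 1)) with average ranks for ties and the
Blom offset c = 3/8, the most common convention in QTL work (configurable).

Composite traits are selected by iterative greedy pruning of the two
donor-level Pearson correlation matrices (one per context): count each
trait's neighbors at |r| ≥ 0.9 summed across both matrices, retain the
max-count trait (ties: lexicographically smallest name, for determinism),
remove it and all its neighbors, repeat; remaining zero-neighbor traits are
all retained. Neighbor relations use |r| (anti-correlated pairs are equally
redundant; a signed mode exists), and removal applies if the pair exceeds
the threshold in *either* matrix — this is the reading that guarantees the
retained set satisfies r < 0.9 pairwise in both contexts, and the
post-condition is asserted on every run. Pseudo-bulking averages well
values per donor. INT is applied at well level before pseudo-bulking.

## Variance decomposition

Each well-level gaussianized trait is decomposed with a crossed
random-intercept mixed model (disease status, source tissue, sex, plate,
well position, edge flag, donor identity) plus fixed covariates (age,
ancestry PCs 1–4, and mean neighbor count in the colony context). REML is
computed directly: with V = σ²(I + Σ_f γ_f Z_f Z_f'), β and σ² are profiled
out and the residual likelihood is optimized over log γ_f (L-BFGS-B,
bounds −14…8 on log γ, extra starts only if the first fails). The log
parameterization is boundary-safe; Z_f Z_f' products are precomputed. This
is implemented in-package because no installed Python library fits multiple
*crossed* random intercepts cleanly; the single-factor case is verified
against the closed-form balanced one-way ANOVA estimator, with which REML
coincides at interior solutions.

Reported fractions are component variance / total, where total = Σ random
variances + residual + the variance of the fitted fixed-effect predictor
across rows; fractions sum to 1 by construction. Per random factor the
p-value is a likelihood-ratio test against the boundary mixture
0.5·χ²₀ + 0.5·χ²₁ (the standard null for one variance tested at zero);
fixed terms get GLS Wald t-tests. Bonferroni correction multiplies by the
number of tested traits.

Estimand note: with few factor levels (7 plates), the *realized* variance
of the drawn plate effects differs from its expectation by far more than
any estimator's error (sd ≈ f·√(2/L)). Recovery tests therefore compare
estimates against the realized per-component fractions, which the
well-level simulator reports; generator-calibration tests average estimates
across independently drawn traits. A per-trait ±0.05 check against the
*requested* fraction of a 7-level component would fail for a perfect
estimator and is not asserted.

## Genotype processing

Common-variant QC applies structural filters first (autosomal, biallelic,
unique position, indels ≤ 5 bp, FILTER = PASS), drops donors with > 10%
missingness, then excludes variants with MAF < 5%, missingness > 5%, or
Hardy-Weinberg exact p < 1e-5. The HWE test enumerates heterozygote counts
conditional on allele counts via the stable probability recurrence and sums
probabilities ≤ the observed configuration's (two-sided); it is verified
against an independent log-factorial enumeration for every genotype
configuration with n ≤ 50.

LD pruning is greedy within sliding windows: base-pair mode (r² > 0.1,
50 kb window, 10 kb step; used before the GRM) and count mode (r² > 0.2,
50 variants, shift 5; used before the common-variant mixture fit). Within a
window the higher-r² pair loses its smaller-MAF member (tie: later
position), mirroring PLINK's convention. Long-range-LD exclusion regions
(0-based half-open BED) are removed first. MAF is computed on observed
genotypes; missing dosages are mean-imputed for r², GRM, and PCA only.

The GRM follows the GCTA convention G = (1/M) Σ (x−2p)(x−2p)'/(2p(1−p));
ancestry PCs are the top eigenvectors scaled by √eigenvalue with the
largest-magnitude loading made positive (deterministic across LAPACK
builds). Burden collapsing selects autosomal PASS variants with call rate
> 95%, MAF < 1%, and HIGH/MODERATE impact; a donor carries a gene iff it
has ≥ 1 qualifying alternate allele, and genes below
ceil(0.02 × n donors) carriers are dropped (ceil gives the floor of 6 at
297 donors).

## Association

Both arms share one covariate model: gaussianized donor-level trait ~
predictor + age + sex + PCs 1–4 + plate indicators (+ donor mean neighbor
count in the colony context). Plate enters as fixed categorical indicators
rather than a random intercept: at donor level with a handful of plates
this is the fixed-effect absorption equivalent of a fast linear-regression
GWAS engine, which is what such scans use. The scan residualizes traits and
predictors on the shared covariates via one QR decomposition
(Frisch–Waugh), giving per-pair statistics exactly equal to the full OLS
fit with the correct residual degrees of freedom — verified against an
independent QR reference to 1e-10. Predictors collinear with the
covariates are flagged (NaN statistics) rather than silently fit; variants
with missing dosages are tested on the observed donors only.

Thresholds are pure Bonferroni: α/n_tests (0.05/(246×9105) = 2.2e-8 for the
burden scan at full scale; 5e-8/246 = 2e-10 genome-wide and 1e-5/246 =
4.1e-8 suggestive for the common scan; raw 1e-6 suggestive for burden).
Genomic inflation is λ = median(χ²₁ quantiles of 1−p)/0.4549. Permutation
nulls shuffle donor labels on one side (traits for the rare arm, genotypes
for the common arm) with a seeded RNG and re-run the full scan.

End-to-end detection tests use the fixed headline threshold 2.2e-8 at desk
scale. Using a family-wise α = 0.05 Bonferroni threshold instead would
allow a ~5% per-seed false-positive rate by construction, which no
"almost never a null hit" check can survive; the fixed threshold makes the
per-seed false-positive probability ≈ n_tests × 2.2e-8 ≈ 1e-5. A planted
effect must be recovered whenever the analytic noncentral-t power bound at
the realized standard error says detection power ≥ 0.999 (with a 0.7
allowance for INT rescaling of the cell-scale effect); β-recovery
calibration (±2·SE coverage) is run on pseudo-bulk means without INT, since
pseudo-bulking preserves the planted scale unbiasedly while INT rescales by
the realized total SD. Coverage is asserted within the 3σ binomial band
around the nominal 95.45% rather than at a hard 95% line, which a correct
implementation would fail ~40% of the time at 200 replicates.

## Effect-size mixture and power projection

Standardized statistics z = β̂/se concatenated across all traits are
modelled as a zero-mean Gaussian scale mixture
z ~ Σ_k π_k N(0, N·τ²_k + 1), where τ²_k is the per-sample true-effect
variance of component k and the +1 is sampling noise; component 0 is a
pinned null spike (τ² = 0), K defaults to 4. Fitting is maximum likelihood
by EM (convergence: log-likelihood change < 1e-8; on large inputs restarts
are selected by a short EM on a 20k subsample before one full-tolerance
run). The no-LD marginal model is an exact Gaussian scale mixture, for
which EM is a transparent, testable ML estimator; this is a deliberate
methodological substitution for the Fourier-regression machinery of the
original mixture estimator, appropriate here because rare variants carry
essentially no LD. Components whose marginal variance lies within 3·√(2/n)
of 1 — inside the sampling resolution of a variance estimated from n draws
— are merged into the spike, since the weight split among
noise-indistinguishable components is not identified; this also produces
the expected "all mass to the null" behaviour on underpowered input.

Projection to sample size N′ evaluates
Σ_k π_k · 2Φ(−z*/√(N′τ²_k + 1)) at z* = Φ⁻¹(1 − p*/2); the spike
contributes exactly p* (the false-positive construction of the threshold),
and expected counts multiply by the number of tests. The single-component
case is verified against adaptive quadrature to 1e-12, and the projection
at the fitted N reproduces the observed significant fraction of the input
within Monte-Carlo tolerance.

## Pipeline, problem sizes, determinism

`run_pipeline` sequences simulate → genotype QC/GRM/PCA/burden → profile
processing per context → variance decomposition → both association arms in
both contexts → mixture fit and projection, writing every stage output plus
a manifest with the configuration hash and per-file SHA-256 checksums.
Identical configurations reproduce identical checksums for all data
artifacts.

Test and acceptance runs use desk-scale cohorts (60–150 donors, 6–12
traits, tens of genes with many ultra-rare variants each; the
variance-recovery grid runs at 100 donors × 6 wells; the mixture fit at
100,000 z-scores; end-to-end recovery over 60 seeds), chosen so the whole
suite exercises every stage at meaningful power on a single CPU. The
variance-component REML is dense (one Cholesky of an n×n matrix per
objective evaluation) and comfortable up to a few thousand wells; larger
cohorts should decompose a subset of traits or thin wells.

## Known limitations

- The REML fitter assumes no missing responses and ≥ 2 levels per factor;
  it reports non-convergence rather than silently returning zeros.
- Burden and common scans are OLS; a GRM-based mixed-model scan
  (fastGWA-mlm style) is out of scope, so strong cryptic relatedness in
  real data would not be absorbed.
- LD pruning advances windows over the original variant list; PLINK's exact
  retained-list window bookkeeping can differ on adversarial fixtures,
  though both satisfy the same pairwise-r² post-condition, which is what
  tests assert.
- The effect-size mixture assumes exchangeable tests across traits when
  concatenating summary statistics and ignores LD entirely; for common
  variants this is only appropriate after aggressive pruning.
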