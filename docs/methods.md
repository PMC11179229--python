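# Methods

`mtgwas` implements a two-stage analysis of multi-trait field and
phenotyping-platform data from an inbred association panel: per-trial mixed
models that turn plot observations into adjusted line means, followed by a
three-step multi-trait genome-wide association scan with a structured
between-trait genetic covariance. A founder-mosaic simulator generates
panels and trials with known truth so that every stage is testable without
external data.

## Stage 1: trial mixed models

Each trait is analyzed under the design it was collected in:

* **Lattice** (replicated incomplete blocks with checks):
  `y_ijk = mu + R_j + B_k(j) + Chk_i* + G_i + e_ijk`, replicate and check
  fixed, block random within replicate.
* **RCBD**: `y_ij = mu + B_j + G_i + e_ij`, block fixed.
* **Augmented** (unreplicated test lines, repeated checks):
  `y_ij = mu + B_j + Chk_i* + G_i + e_ij`, block random, checks fixed.

The line effect is fitted twice: random, to estimate the genetic variance
`sigma_g^2`, the line BLUPs and their prediction-error variances (PEV); and
fixed, to produce BLUEs (adjusted means) for association mapping. One REML
engine serves all three designs: the residual variance is profiled out and
the optimizer (Nelder–Mead) works over the one or two log variance ratios of
the declared random terms; BLUPs and PEVs come from Henderson's mixed-model
equations at the REML estimates. Right-skewed volume/count traits (convex
hull, median roots) take a natural-log transform before fitting.

Generalized heritability follows Cullis:
`H^2 = 1 - vbar(BLUP) / (2 sigma_g^2)`, where `vbar` is the mean over all
line pairs of `Var(BLUP_i - BLUP_j)`, computed exactly from the PEV matrix
(n^2 pairs is cheap at panel scale). `H^2` is defined as 0 when
`sigma_g^2 = 0` and clipped to [0, 1]. On a balanced RCBD this reduces
exactly to the entry-mean heritability `sigma_g^2 / (sigma_g^2 +
sigma_e^2/r)`, which the tests verify to 1e-6.

BLUEs are standardized per trait to mean 0 and unit sample variance (n−1
denominator) before the multi-trait scan; unscored line × trait cells stay
missing.

## Multi-trait null model (step 1)

For line i and trait t,

    y_it = mu_t + G_it + e_it,
    vec(G) ~ N(0, K ⊗ Sigma_T),    e ~ N(0, I ⊗ Sigma_R),

with `K` the VanRaden genomic relationship matrix
(`K = WW' / (2 Σ p_j(1−p_j))`, `W` the frequency-centered {0,2} calls) and
`Sigma_R` diagonal (no residual covariance across traits — the traits come
from separate experiments). `Sigma_T` is parameterized three ways:

* **FA1**: `Λλ' + diag(Ψ)`, rank-1 loadings — 3T covariance parameters;
* **FA2**: rank-2 loadings with `Λ[1,2] = 0` for rotational identifiability
  — 4T−1 parameters;
* **UNS**: unstructured via a Cholesky factor — T(T+1)/2 + T parameters.

Fitting is REML with fixed effects profiled. With complete trait data the
restricted likelihood is evaluated in the eigenbasis of `K`: rotating by the
eigenvectors de-correlates lines, leaving n independent T-variate normals
with covariance `d_i Sigma_T + Sigma_R` — an O(nT^3) evaluation — and an
analytic gradient is propagated through the loadings/Cholesky/log-variance
parameterization, which makes a study-scale fit (n ≈ 272, T = 8) take a few
seconds. With missing cells the exact observed-cell dense restricted
likelihood over the explicit Kronecker covariance is used instead (feasible
at n ≈ 300, T = 8; exactness preferred over EM completion for the null fit).

Numerical choices: variances live on the log scale and loadings are boxed in
[−6, 6] (traits are standardized, so larger values are implausible); starting
values take half the sample trait covariance projected onto each family by
eigen-truncation; L-BFGS-B runs up to 500 iterations with as many as five
restarts from the best iterate, declaring convergence when a restart improves
the restricted log-likelihood by less than 1e-8 (relative). Restarts matter
because line searches can abort on the flat boundary where a residual
variance approaches zero.

The structure is chosen by AIC = −2·loglik + 2k over the REML
log-likelihood, counting covariance parameters only — all candidates share
the same fixed effects, so the comparison is valid. Exact AIC ties break to
the fewer-parameter model. Note that FA2 is only more parsimonious than UNS
for T ≥ 5; on the eight-trait panel the AIC comparison is a real contest
(UNS has 44 parameters, FA2 31).

## Association scan (steps 2–3)

**Step 2 — GLS scan.** Each SNP enters with trait-specific fixed effects,

    y_it = mu_t + x_ir α_rt + G_it + e_it,

with `(Sigma_T, Sigma_R)` frozen from the selected null fit and the kinship
replaced per chromosome by its leave-one-chromosome-out (LOCO) version:
markers on the tested chromosome do not contribute to the polygenic
correction, avoiding proximal contamination/over-correction. One
eigendecomposition per chromosome is reused across all its SNPs; per SNP the
GLS normal equations are 2T × 2T. The joint test is the Wald statistic
`α̂' Var(α̂)^{-1} α̂` referred to chi-square with T degrees of freedom (one
effect per trait; the reference distribution is a package choice, documented
here). Monomorphic SNPs and singular effect covariances are skipped with a
log entry.

**Thresholds.** The effective number of independent tests is the genome
length divided by the average LD extent (default 659 Mb / 150 kb ≈ 4,393),
giving `-log10(0.05 / 4393) = 4.94` as the genome-wide significance
threshold; 4.0 marks suggestive associations. A SNP exactly at 4.94 is
significant (≥ rule).

**Step 3 — refit.** Every significant or suggestive SNP is refitted one at a
time by full REML with the SNP as a trait-specific fixed covariate, so all
variance components are re-estimated conditional on the SNP. Reported per
trait: effect (standardized-trait units per allele-code unit), standard
error, 95% CI as `α̂ ± 1.96 SE` (normal approximation), per-trait Wald p
(`chi2_1`), and the favorable allele — minor when `α̂ > 0` under the
0 = major / 2 = minor coding. If the refit fails to converge the GLS
estimates under the null covariance are reported with a fallback flag.

**Variance explained.** For allele frequency p the {0,2} genotype variance
is `4p(1−p)`, so a SNP explains `100 · α̂² · 4p(1−p) / V_pnull` percent of
trait variance, with `V_pnull` the trait's total (genetic + residual)
variance from the *null* fit rather than assumed 1 after standardization.
It is computed for suggestive as well as significant SNPs.

## LD characterization

For an inbred panel the genotype table of a SNP pair is its haplotype table,
so LD is measured as the squared Pearson correlation of the {0,2} codes
(pairwise-complete over missing calls) and its significance by a two-sided
Fisher exact test on the 2×2 class table. Neighborhoods collect all SNPs
within a closed ±2,000-kb window of each associated SNP plus all
same-chromosome pairs of associated SNPs.

## Synthetic panel generator

Each chromosome of each line is a mosaic of founder haplotypes (founder
alleles iid Bernoulli(1/2); 24 founders by default, emulating the many
ancestral haplotypes of a diversity panel). Segment lengths are exponential;
because two sites share a founder with probability `exp(−d/L)` for segment
mean `L`, the r² correlogram decays as `exp(−2d/L)`, so the generator sets
the breakpoint rate to `1/(2·ld_segment_bp)` and `ld_segment_bp` is the
**target r² e-folding distance** (150 kb by default; the fitted decay on a
simulated panel lands within a few percent of target). SNPs below the MAF
floor are dropped; missing calls can be injected at a configurable rate.

Genetic values are `XA + U`: centered QTL genotype columns times per-trait
effect matrices, plus a polygenic background with `vec(U) ~ N(0, K ⊗
Sigma_T_true)` using the panel's own kinship. The default study covariance is
a two-factor structure over eight traits (grain yield; root surface area and
diameter; shoot dry weight and P content; centroid, median roots, convex
hull) with a broad root-vigor factor and a diameter-contrast factor, implying
moderate positive architecture correlations, a strong shoot-trait
correlation and weak grain-yield links. Trials add realized replicate/block
effects and plot noise under the three designs (lattice 3 reps, 11-entry
blocks with 2 checks; RCBD 3 reps; augmented 14 blocks with checks ATF8/ATF10
in every block); the study panel is 272 lines, 10 chromosomes × 500 SNPs and
five pleiotropic QTL with effects on overlapping 2–4-trait subsets
(|effect| ≈ 0.36–0.54 latent-scale units).

What the generator does *not* emulate: population structure/subpopulations,
allele-frequency spectra of real GBS data, genotyping error, selection, or
epistasis. Passing tests therefore demonstrate correctness of the estimators
and calibration of the tests under the stated model, not robustness to
structure confounding — the scan corrects relatedness only through kinship,
as in the original design.

## Calibration conventions in the tests

The type-I calibration study draws each chromosome's polygenic background
under the covariance the chromosome-specific scan assumes (its LOCO
kinship). Generating a single phenotype from the full-genome kinship and
scanning with LOCO kinship is anticonservative *by construction* — the
tested chromosome's polygenic share becomes an unmodeled confounder — which
is precisely the power-for-calibration trade LOCO makes; the calibration
test instead asks whether the GLS statistic has its nominal distribution
under its own null, which it does (KS-uniform p-values, exact empirical
levels at 1e-3 and 1e-4). A fresh null phenotype is drawn per 20-SNP batch:
pooling thousands of p-values that share a handful of phenotype
realizations over-disperses the KS statistic even when each test is
perfectly calibrated, so the simulation keeps the pooled p-values close to
independent.

## Problem sizes

Simulation studies run at: study scale 272 lines × 5,000 SNPs × 8 traits
(pipeline and acceptance script); calibration 300 lines × 2,000 SNPs × 4
traits; parameter recovery n = 500 (100 replicates, UNS) and T = 6, n = 400
(100 replicates, AIC selection); power 200 replicates at n = 400; end-to-end
fixture 200 lines × 2,000 SNPs × 4 traits × 3 QTL over 10 seeds. These sizes
are the package's chosen desk-scale study conditions; the estimators
themselves have no size assumptions beyond memory.

## Known limitations

* The missing-cell likelihood is exact but dense — O((nT)³) per evaluation —
  so null fits on panels much larger than n ≈ 300 with missing traits are
  slow; complete-data fits use the fast eigen-rotated path.
* The scan treats `(Sigma_T, Sigma_R)` as known from the null fit (the
  standard two-step GLS approximation); p-values ignore their estimation
  error.
* `chi2_T` for the joint Wald test and the 1.96 normal multiplier for CIs
  are asymptotic conventions; at very small n a finite-sample reference
  would be preferable.
* The AIC comparison assumes all candidate structures are fitted to the same
  missingness pattern (they are, by construction, within one run).
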