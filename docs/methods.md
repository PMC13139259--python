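# Methods

## Study design and model

The package targets panels of fully inbred lines (F ≈ 1) raised in two
dietary environments, with replicate pooled samples per line × diet cell.
Because lines are inbred, among-line variance captures the total genetic
variance, so all heritabilities are broad-sense.

Diversity and abundance traits are analysed on a Gaussian scale obtained by
the rank-based inverse normal transformation (INT),

    INT(u_i) = Φ⁻¹((rank(u_i) − 0.5) / n),

applied once per trait to the diet-pooled per-sample values, with average
ranks for ties. The two-diet model is

    y = μ + L + D + L×D + e,

diet fixed, line and line×diet random, residual Gaussian. The per-diet
reduced model is the one-way random-effects model y = μ + L + e, whose
components σ²_G (line) and σ²_e (residual) define H² = σ²_G/(σ²_G+σ²_e).

Assumptions worth stating: line effects are exchangeable Gaussian draws (no
relatedness structure between lines is modelled); residuals are homoskedastic
within diet; replicates are conditionally independent given the line × diet
cell. Pooled samples mean "residual" includes both pool composition and
sequencing noise.

## REML implementation

Line and line×diet effects never connect observations from different lines,
so the marginal covariance matrix is block-diagonal by line, with per-line
blocks

    V_i = σ²_L J + σ²_L×D B + σ²_e I,

where J is all-ones and B indicates shared diet. The restricted likelihood
is accumulated block-wise; lines with identical within-line diet patterns
share one block inverse, so a balanced 88-line × 2-diet × 3-replicate fit
costs one 6×6 Cholesky per likelihood evaluation. Fixed effects are
profiled out; the criterion includes the log-determinant of X'V⁻¹X, so
restricted likelihoods are comparable across fits with the same fixed
effects.

Optimisation is Nelder–Mead over log-variances (floor 1e-12, i.e. an
effective zero), started from the method-of-moments ANOVA estimators plus
cruder fallbacks; additional starts are skipped once two independent starts
agree to 1e-9 in the criterion. Components below twice the floor are
reported as exactly 0. On balanced designs with interior solutions the
estimates coincide with the closed-form ANOVA method-of-moments estimators
(verified to 1e-6 in the tests) and with statsmodels' MixedLM.

The asymptotic covariance of the variance components — required for the
delta-method SE of H² — is the inverse observed information on the variance
scale, computed by central finite differences of the restricted
log-likelihood at the optimum (relative step 1e-5). When a component sits
on the zero boundary the information matrix can be near-singular; a
pseudo-inverse is used and the resulting intervals should be read
cautiously, which is the usual price of boundary estimates.

## Heritability and its uncertainty

H² = σ²_G/(σ²_G+σ²_e); Var(H²) from the delta method with
∂H²/∂σ²_G = σ²_e/(σ²_G+σ²_e)² and ∂H²/∂σ²_e = −σ²_G/(σ²_G+σ²_e)², using the
full 2×2 component covariance including its off-diagonal term. The CI is
H² ± 1.96·SE and may extend beyond [0, 1], as asymptotic intervals on a
ratio do; no truncation is applied. In the test suite the delta SE is
checked against a 2,000-draw parametric bootstrap (within 10% relative) and
its CI coverage against 500 simulated panels (within [0.90, 0.98]).

## Genotype-by-diet interaction and diet effect

GDI is a restricted-likelihood-ratio test of σ²_L×D = 0 between nested REML
fits sharing the same fixed effects. Because the null value lies on the
boundary of the parameter space, the default reference distribution is the
½χ²₀ + ½χ²₁ mixture (plain χ²₁ is available as an option, and is
conservative). The diet fixed effect is tested by a likelihood-ratio test
on maximum-likelihood fits with and without the diet term; a paired
per-line-mean t-test (the balanced-ANOVA F of diet against the line×diet
stratum) is the alternative `method="f"`.

## Genetic and phenotypic correlations

Two estimators of the cross-diet genetic correlation are exposed:

* the variance-component plug-in ρ_G = σ²_L/(σ²_L + σ²_L×D), which is
  downward-biased when genetic variances differ between diets because the
  interaction component then absorbs scale heterogeneity;
* the covariance form ρ_G = σ_Gij/√(σ²_Gi·σ²_Gj), with per-diet genetic
  variances from the single-diet REML fits and σ_Gij the sample covariance
  of per-line means across diets. Since the two diets use different
  individuals, residual sampling errors are independent between diets and
  the line-mean covariance estimates the genetic covariance without bias.

The covariance-form estimate is deliberately not clamped to [−1, 1]:
sampling noise in the denominator can push it past 1, and truncating would
bias the reported magnitudes. As a ratio of noisy estimates it carries a
small positive finite-sample bias at panel sizes near 88 lines; the
recovery experiment (`recovery_experiment`) quantifies this directly, and
the Yamada plug-in — essentially unbiased in the same experiment — is
summarised alongside it.

Standard errors for both genetic estimators use SE = (1−ρ²)/√(n−3) with n =
number of lines, and the CI is the untransformed ρ ± 1.96·SE. Phenotypic
correlations are Spearman's ρ (average ranks), same SE formula with n = the
number of paired observations, but the CI is built on the Fisher-z scale,
z = ½ln((1+ρ)/(1−ρ)), transforming z ± 1.96·SE back through tanh. Keeping
the genetic CI untransformed and the phenotypic CI z-transformed mirrors
the reporting conventions the pipeline targets. A perfectly monotone pair
has infinite z; the CI collapses to [ρ, ρ] and the estimate is flagged.

## QC conventions

* Depth filter: samples with total reads **equal** to the threshold are
  retained (inclusive boundary; default 1,000 reads).
* Good's coverage: 100·(1 − n₁/N_T) with n₁ the count of single-read OTUs.
* Endosymbiont exclusion matches the genus field case-insensitively and is
  applied before diversity and abundance computation (a flag computes
  diversity pre-exclusion instead). Samples emptied by the exclusion are
  retained with zero reads and flagged, so the caller decides their fate;
  the pipeline drops them.
* The concordance AUC is the Mann–Whitney probability that a sample from a
  known-infected line carries more endosymbiont reads than one from an
  uninfected line (ties ½), computed per diet with a combined option — per
  diet because sequencing batches and depths can differ by diet.

## Diversity conventions

Simpson's index uses the finite-sample form 1 − Σn(n−1)/(N(N−1)) on
absolute counts (the probability two reads drawn without replacement differ
in OTU), not the plug-in 1 − Σp². Shannon is the standard non-negative
−Σ p ln p in natural-log units. Rarefaction offers the exact hypergeometric
expectation of richness and a Monte-Carlo subsampling check.

## Ordination

Five presentation transforms: Euclidean (identity), Chord (unit-norm rows),
Aitchison (CLR after a +1 pseudocount — a fixed, documented choice since
CLR is undefined at zero), Robust Aitchison (CLR over each row's nonzero
support), and the chi-square correspondence standardization. PCA is the
SVD of the column-centred matrix. CCA is classical: the chi-square
standardized matrix is projected, with row-mass weights, onto the
constraint's dummy design; the fitted part's SVD gives the constrained axes
and the residual's the unconstrained ones, with axis shares against total
inertia (conserved to 1e-8). Because CCA's intrinsic metric is chi-square,
a Euclidean-metric analogue (redundancy analysis) is provided separately
rather than pretending CCA can run under other metrics. Axis signs are
fixed by orienting each axis so its largest-magnitude loading is positive.

## Association screen

Features (alpha-diversity, PCA1/PCA2, prevalent-taxon abundances) and
age-related traits are both reduced to line means within each diet, so
lines — not samples — are the correlation units. Each (feature, trait, age)
pair gets a Spearman ρ with the Fisher-z CI; a pair is "significant" when
the CI excludes zero. Traits are screened per age rather than as age
slopes. Benjamini–Hochberg q-values are reported as an additional column
but do not drive the flag, matching a CI-based reporting style; users who
want FDR control can threshold the q-value column.

The prevalence filter keeps taxa whose mean relative abundance reaches the
threshold (default 1%) in at least one diet, computed over samples within
each diet (an option averages within lines first). At species rank,
unknown species are labelled "unclassified <genus>" and can be dropped.

## Synthetic data

The generator exists so that every estimator can be exercised with known
truth. Two paths are kept separate on purpose:

* **Trait path** (`simulate_trait_table`): draws directly from the Gaussian
  mixed model, defaults 88 lines × 2 diets × 3 replicates with variances
  (σ²_L, σ²_L×D, σ²_e) = (0.3, 0.1, 0.6) — a total near 1 as on the INT
  scale, implying per-diet H² = 0.4 and ρ_G = 0.75. This isolates estimator
  behaviour from transformation distortion.
* **Count path** (`simulate_otu_table`): a low-complexity community
  dominated by one lactic-acid genus (~48% baseline) with a second
  acetic-acid genus (~20%) and a tail of minor genera; per-(line, diet)
  latent genus log-abundances receive Gaussian line, diet and line×diet
  effects; each sample draws Dirichlet-multinomial counts at a
  negative-binomial depth (mean 20,000, floor just above the 1,000-read
  cutoff, with an option to inject sub-threshold samples so the filter has
  work); rare tail OTUs supply singletons for coverage; a binary per-line
  endosymbiont status spikes Wolbachia reads (~30% of reads in infected
  samples, rare index-hopping noise elsewhere).

Age-trait tables are coupling·z(feature) + √(1−coupling²)·noise per diet
and age, so coupling 0 is an exact null for the screen and coupling 1 a
deterministic positive control.

What the generator does **not** emulate: phylogenetic correlation among
OTUs, read-level error/chimera processes, depth-composition coupling,
non-Gaussian line-effect distributions, and spatial/temporal batch
structure. Passing tests therefore certify the estimators under their own
assumptions, not robustness to violations of them.

All randomness flows through numpy's default PCG64 generator from explicit
seeds; repeated runs are bit-identical.

## Problem sizes in the shipped tests

The recovery experiment uses 500 simulated panels at the 88 × 2 × 3 design;
GDI type-I calibration uses 1,000 replicates; the screen null uses 40
replicate studies (≈3,000 pairs). These sizes put Monte-Carlo error well
below the tolerances being asserted while keeping the whole suite around
five minutes on one core.

## Known limitations

* The observed-information covariance is unreliable when components sit at
  the zero boundary; SEs there are indicative only.
* The covariance-form genetic correlation is consistent but not unbiased;
  at 88 lines its mean sits slightly above the truth (see the recovery
  experiment), a property of the ratio form rather than of the fit.
* ML-based likelihood-ratio tests of fixed effects are mildly
  anticonservative in small panels; the paired `method="f"` variant is the
  safer choice below ~30 lines.
* BIOM-format input is not implemented; the three-TSV dialect is the
  supported interchange format.
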