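# Methods

This note documents the statistical procedures implemented in `lipidmeth`,
the assumptions behind them, what the synthetic cohort does and does not
emulate, and the numerical choices that make results bit-reproducible.

## 1. Synthetic twin cohort

The generator produces a two-visit cohort of twin pairs with the moments a
middle-aged population twin registry would show: pair-shared age ~ N(50, 10²)
(+4.67 years at follow-up), pair-shared sex (P(male) = 0.68), individual
smoking (never/former/current = 0.54/0.13/0.33) and alcohol
(0.51/0.07/0.42), BMI ~ N(24.5, 3.5²) with a 30% pair-shared variance
component, and a default 70% MZ fraction.

**Lipids** are generated on the natural-log scale and exponentiated, so the
pipeline's log transform recovers Gaussian working variables. Log-scale
locations/scales — TG (0.45, 0.50), TC (1.565, 0.21), HDL-C (0.27, 0.26),
LDL-C (0.87, 0.30) mmol/L — give means near 1.85/4.9/1.36/2.5 mmol/L.
Covariate effects on the log scale (per year of age, male sex, current
smoking, current drinking, per BMI unit) are small and lipid-specific, e.g.
TG: (0.003, 0.15, 0.05, 0.05, 0.02); they exist so that residualization has
something real to remove. Each lipid's standardized residual process has a
within-pair ICC of 0.3 and autoregression 0.6 across visits unless a
cross-lagged parameter set overrides it.

**Methylation** is generated on a logit-like latent scale — per-CpG location
m0 ~ N(0, 1.5²) and slope 0.35, squashed through the logistic function —
which keeps beta-values in (0, 1) and produces the U-ish marginal
distribution of array data. The latent process has unit variance with a
pair-shared component of variance `icc_mz` (default 0.6) or `icc_dz` (0.3)
by zygosity, at both visits. Contamination is added on the beta scale:
per-CpG loadings ~ N(0, 0.05²) on centered cell proportions (six leukocyte
types from a Gran-dominant Dirichlet), per-CpG batch offsets ~ N(0, 0.02²)
(centered across batches), and measurement noise N(0, 0.01²), then clipping
to [1e-4, 1−1e-4].

**Cross-lagged and mediation structure** is imposed on the latent scales:
a signal CpG's follow-up latent is `auto_meth·z_b + rho1·lipid_b + resid`,
and a driven lipid's follow-up residual is `auto_lipid·r_b + rho2·z_b +
resid`. At most one CpG may drive a given lipid through ρ2, so the lipid
follow-up equation stays well-defined; further CpGs on the same lipid may
carry ρ1 or cross-sectional (EWAS) effects, which do not conflict. The
mediation triple injects `a·X_b` into the mediator's follow-up and
`b·M_b + c′·X_b` into the outcome lipid's follow-up, with X the standardized
BMI process. Cross-sectional EWAS signal is planted directly on the beta
scale (slope per unit log-lipid), so the EWAS estimand matches the planted
coefficient without squash attenuation.

**SNP-overlapping probes** (59 by default) get genotypes by explicit
parental transmission: MZ co-twins share the genotype at every probe; DZ
co-twins inherit each parental allele independently (shared with probability
1/2). Dosages map to beta modes {0.05, 0.5, 0.95} plus N(0, 0.03²) noise.
With these defaults MZ co-twin correlations sit above 0.95 and DZ below 0.85
in ≥99% of pairs, so the 0.90 calling cutoff separates cleanly.

**What is not emulated:** raw array intensities and normalization,
genome coordinates (beyond a sex-chromosome flag in the QC generator),
probe-probe spatial correlation, non-Gaussian lipid tails beyond
log-normality, age-related drift of methylation, and informative dropout
(follow-up attrition is a uniform random subset of whole pairs via
`followup_fraction`). Passing tests therefore demonstrate correctness of the
estimators under the stated generating process, not robustness to every
pathology of real array data.

## 2. Preprocessing

Probe filters use the standard 450K/EPIC thresholds: detection p > 0.05 in
more than 1% of samples; bead count < 3 in more than 5% of samples; non-CpG
or multi-hit probes; SNP-related probes (MAF > 0.05); sex-chromosome probes.
Filters are applied in that order and a probe is reported once, under the
first filter that catches it. Sample exclusions: lipid-lowering medication
(removes all of that participant's specimens), any missing lipid, and a
provided sex-mismatch flag.

Lipid outliers beyond 3 SD of the mean are set to missing **on the raw
scale, in a single pass** (means/SDs are not re-estimated after trimming;
sample SD, ddof = 1), then values are natural-log transformed. Trimming
before the log matches the order in which a lab pipeline sees the data; the
alternative (trim after log) would retain heavy right-tail values.

Zygosity is called per pair as Pearson correlation across SNP-probe betas,
MZ iff r > 0.90; singleton pairs and zero-variance vectors are `unknown`.

Cell/batch adjustment, used only for the CLPM phase (the EWAS models cells
and batch as covariates instead): per probe, the least-squares fit on
centered cell proportions is subtracted (intercept kept, so probe means are
preserved); then each batch is location/scale standardized probe-wise to the
pooled mean/SD. This exact standardization replaces ComBat's
empirical-Bayes shrinkage: with generous per-batch sample sizes and only
batch-free residuals needed downstream, shrinkage buys nothing and exactness
makes the invariants testable. Batches with fewer than 3 samples are
rejected.

## 3. Per-CpG linear mixed model

The EWAS model is a random-intercept-per-twin-pair regression estimated by
REML. The fitter profiles the likelihood to one dimension in
γ = σ²_pair/σ²_resid: an orthonormal Helmert rotation within each cluster
makes the marginal covariance diagonal (contrast components with variance
σ², cluster-mean components with variance σ²(1+sγ) for cluster size s), so
each REML evaluation is a weighted least-squares solve on per-size
cross-products. Cross-products involving the design alone are cached and
shared across all CpGs, which is what makes a 20,000-CpG screen take tens of
seconds rather than hours. The 1-D search is bounded Brent on γ ∈ [0, 200]
(xatol 1e-7); estimates within 1e-5 of 0 are snapped to the boundary
(variance 0) and flagged. All-singleton data reduce to OLS with a log
notice. A zero-residual fit (response in the design span) is reported as a
rank-deficiency error by `fit_lmm_single`.

Inference on the lipid coefficient is a Wald z-test (normal reference):
with cohort-scale n the difference from Satterthwaite/Kenward–Roger degrees
of freedom is negligible, and the normal reference keeps the screen fast and
deterministic. Surrogate variables are not estimated; the known batch and
cell-proportion covariates of the synthetic cohort play that role as fixed
effects. λ uses the median definition; p-values of exactly 0 are clipped to
the smallest positive float with a warning. BH-FDR is applied across all
CpGs tested within one lipid × model run.

Replication: an association is replicated iff FDR-significant in both stages
with the same coefficient sign; CpGs absent from the replication panel count
as not replicated.

## 4. Cross-lagged panel model

Variables enter as residuals (Section 5), so the mean structure is ignored:
columns are centered and the likelihood is fitted to covariances with
divisor n. With freely correlated baselines and freely correlated
disturbances the two-variable CLPM is **saturated**: the ML path estimates
equal per-equation least squares exactly, the implied covariance reproduces
the sample covariance, and SRMR = 0, CFI = 1 identically — the estimator
computes the per-equation solution directly and a numerical
concentrated-likelihood oracle confirms the identity in the tests. Fit
statistics use T = n·F_ML (not (n−1)·F_ML) so they are bit-reproducible;
model-vs-baseline discrepancies below 1e-9 are treated as exact fit, which
pins the saturated model at CFI = 1 rather than 1−1e-16.

Cluster-robust standard errors are the CR0 sandwich over twin pairs
(per-pair score sums, no small-sample correction), with CR1 (G/(G−1)) and
classical SEs as options; singleton participants form their own clusters.
The screen applies BH across all (CpG, lipid, direction) hypotheses within a
zygosity stratum by default (`fdr_scope="lipid"` restricts the family to one
lipid); strata with fewer than 10 pairs are skipped with a warning.

## 5. Residualization

Per visit, lipids (and BMI) are adjusted for age, sex, smoking and alcohol
as fixed effects with a pair random intercept; the **marginal** residual
(observed − fixed-effect fit) is carried forward. Conditioning on the pair
effect as well would absorb the very correlation the CLPM's cluster-robust
inference is meant to handle. A consequence worth knowing: marginal GLS
residuals are exactly orthogonal to pair-constant covariates (complete
pairs), but only asymptotically orthogonal to individual-varying ones —
the residual-by-smoking correlation is O(n^{-1/2}·(γ/(1+γ))), ~0.01 at
n = 160. Methylation residuals (computed on the cell/batch-adjusted matrix)
are additionally Z-transformed within visit (sample SD), separately at
baseline and follow-up. CLPM panels use complete twin data only; BMI is not
among the CLPM-phase covariates (it is the exposure of the mediation phase).

## 6. Mediation

The three structural equations are fitted by per-equation least squares with
regressor sets {X_b}, {M_b, X_b}, {Y_b, M_b, X_b}. A subtlety, verified
numerically: with disturbances left *freely correlated*, exact full-information
ML under the three exclusion restrictions factorizes into sequential
*conditional* regressions and differs from the marginal per-equation solution
by O(1/n). This package defines its estimator as the per-equation solution —
the quantity the field's path-model tables report — and treats the joint
model only through its implied covariance when computing fit indices
(df = 3: the omitted X_f~M_b, X_f~Y_b, M_f~Y_b paths, with free disturbance
correlations).

Effects follow the standard convention: indirect = a·b, direct = c′,
total = a·b + c′ (an identity, not an estimate). The proportion mediated
a·b/(a·b + c′) is reported only for consistent mediation (indirect and total
sharing sign, |total| > 1e-10); otherwise NaN with both components
available. The indirect-effect SE is the first-order delta method
√(b²V_a + a²V_b + 2ab·C_ab) using the cluster-robust cross-equation
covariance from stacked per-pair scores; the proportion SE is the delta
method on the ratio. When both â and b̂ are numerically zero the delta SE
degenerates to 0 and the fit is flagged (`degenerate_indirect_`) — use the
cluster bootstrap (percentile CIs over resampled pairs, seedable, 1999
resamples by default) in that regime.

Mediator screening mirrors the analysis sequence: CpGs whose ρ2 passed the
CLPM screen's FDR are candidates; for each, the BMI↔CpG and BMI↔lipid CLPMs
are fitted first and the mediation model runs only if both BMI→trait paths
are significant (raw p, matching how exposure screens are reported).

## 7. Problem sizes and determinism

Defaults are sized for a laptop: the bundled tests simulate cohorts of
60–500 pairs and 80–20,000 CpGs; the acceptance script uses 100 replicates
of n = 288 (the follow-up sample size) for fit-index calibration, 100
replicates of n = 5000 for mediation-proportion recovery, and one
500-pair × 20,000-CpG null cohort for EWAS calibration — about a minute in
total. Every stochastic routine takes an explicit seed (`numpy` Generator);
identical config + seed gives byte-identical cohorts, manifests and tables.

## 8. Known limitations

- The REML search assumes a single variance ratio shared across clusters;
  heteroskedastic pair effects (e.g. zygosity-specific variances) are not
  modeled in the EWAS — they appear only through the generator.
- CR0 sandwich SEs are mildly downward biased with few clusters; use CR1 or
  the bootstrap below ~50 pairs.
- The delta-method proportion SE is unreliable when the total effect is
  near zero; the bootstrap is the honest alternative there.
- Marginal residualization leaves O(n^{-1/2}) correlation with
  individual-varying covariates (Section 5).
- The median-based λ from m p-values has sampling SD ≈ 1/(2·f(χ²₁ median)·√m)
  ÷ 0.455 (~0.066 at m = 1000, ~0.015 at m = 20,000); single-replicate λ
  values at small m should be read with that spread in mind.
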