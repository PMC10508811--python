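# Methods

`psychstruct` studies the factor structure of comorbid binary conditions at
two levels of analysis — phenotypic (how diagnoses co-occur in people) and
genetic (how the additive genetic components of their liabilities
correlate) — and the consequences of disagreement between the two. Because
individual-level biobank data cannot be redistributed, every estimator in
the package is exercised against a synthetic-data generator whose ground
truth is known in closed form. This note documents the generating model,
each estimator's assumptions and numerical choices, and what the synthetic
results do and do not demonstrate about real data.

## The liability-threshold factor model

For condition *i* of *k*, an individual's liability is

```
L_i = g_i + e_i,        Var(L_i) = 1,   Var(g_i) = h2_i
```

with `g_i` the additive genetic component (liability-scale SNP heritability
`h2_i`) and `e_i` everything else. A diagnosis is `1[L_i > tau_i]` with
`tau_i = Phi^-1(1 - K_i)`; the threshold comes from the *population*
lifetime prevalence `K_i`, so the sample prevalence is an output of the
simulation, not an input.

Both components follow common-factor structures specified on the
standardized scale: `corr(g) = L_g Phi_g L_g' + diag(1 - communality)` and
analogously for `corr(e)`. The implied genetic correlation matrix is
`corr(g)`; the implied phenotypic (liability-scale) correlation is the
h2-weighted mixture

```
r_p[i,j] = sqrt(h2_i h2_j) r_g[i,j] + sqrt((1-h2_i)(1-h2_j)) r_e[i,j].
```

Because the genetic and environmental structures are separately
controllable, the two levels can be deliberately decoupled. Two mechanisms
are provided:

* **structural decoupling** — same indicator blocks, different factor
  correlation matrices (e.g. internalizing and compulsive factors
  correlate 0.45 genetically but 0.89 environmentally). With equal
  heritabilities the phenotypic level remains an *exact* three-factor
  model whose factor correlations are the h2-weighted mixture of the two
  levels' — this is what makes generating loadings well-defined at both
  levels;
* **targeted injection** — `decouple_levels` re-solves the environmental
  correlation matrix so that `r_p - r_g` equals an arbitrary symmetric
  target exactly, raising an infeasibility error (with the offending
  eigenvalue) when no positive-definite environmental structure exists.

**Genotypes.** SNPs are Binomial(2, MAF) with MAF ~ Uniform(0.05, 0.5),
arranged in LD blocks of 40 SNPs. Each block is generated from two
independent latent Gaussian AR(1) haplotype chains thresholded at
`Phi^-1(1 - MAF)`, preserving Hardy–Weinberg margins and yielding a
closed-form expected dosage correlation (`expected_dosage_corr`) used as
the analytic LD oracle in tests. Block decay cycles deterministically over
{0, ¼, ½, ¾, 1} × `ld_decay` (default 0.9): a genome that mixes unlinked
and strongly linked regions is what gives the LD scores enough spread to
identify the LD-score-regression intercept; a single shared decay leaves
slope and intercept nearly collinear. Chromosome labels are assigned
round-robin over 22 autosomes per block (supporting the odd/even split),
with positions spaced 100 kb.

**Genetic liabilities.** Per-SNP standardized effects are drawn once per
model: common-factor columns correlated according to `Phi_g` (each
N(0, Phi_g/M)), plus independent per-condition specific columns. Factor
scores are the effect-weighted sums of standardized dosages, empirically
standardized within the cohort so that liability variances — and hence
population-prevalence calibration — are exact in-sample. Environmental
components are drawn from `corr(e)` directly.

What the generator does **not** emulate: relatedness/GRM structure,
population stratification (so LDSC intercepts are 1 in truth), sex
chromosomes, imputation uncertainty, missing diagnoses (supported by the
estimators, not generated by default), and realistic genome scale
(M is thousands, not millions — see "scale" below).

## Estimators

**Association scans** are ordinary least squares of the 0/1 outcome on
allele dosage plus covariates (Frisch–Waugh residualization; exact
equivalence to joint OLS is asserted against a statsmodels oracle at
1e-8). Linear-probability effects on a binary trait are the standard input
convention for LD-score regression; no mixed-model machinery is needed
because no relatedness is simulated. Effective N is `4 p (1-p) N`;
meta-analysis is sample-size weighted (`w = sqrt(Neff)`,
`z = sum(w z)/sqrt(sum w^2)`), with effective Ns summing across cohorts
and alleles aligned by strand-aware flipping.

**Tetrachoric correlations** use two-step estimation: thresholds fixed at
the normal quantiles of the margins, correlation maximizing the 2×2
multinomial likelihood (Owen's-T bivariate normal CDF; bounded scalar
minimization to 1e-7; estimates capped at ±0.999; zero cells get a 0.5
continuity correction and a flag). Standard errors come from the observed
information. The matrix is assembled pairwise-complete; nearest-PD
smoothing is eigenvalue clipping at 1e-6 followed by re-normalization to a
unit diagonal, and changes matrices whose smallest eigenvalue exceeds
−0.005 by less than 0.01.

**LD scores** are sums of bias-adjusted squared in-sample correlations
(`r2 - (1-r2)/(n-2)`) within a ±60-SNP same-chromosome window; the
simulated cohort plays the role of the reference panel. **LD-score
regression** regresses chi² on `N l / M` with the standard two-component
weights (heteroskedasticity × 1/l overcounting). The plug-ins behind the
weights come from a first-pass unweighted fit and are shared between the
univariate and cross-trait regressions so that the genetic correlation of
a study with itself is exactly 1. Standard errors are delete-a-block
jackknives; the block count defaults to 200 but analyses at M = 2,000 use
50 blocks so a jackknife block is never smaller than an LD block. The
attenuation ratio is `(intercept - 1)/(mean chi² - 1)`, reported as
undefined (the "Ratio < 0" convention) when mean chi² ≤ 1; lambda_GC uses
the chi²₁ null median 0.4549. Liability conversion is
`h2_liab = h2_obs K²(1-K)² / (P(1-P) phi(z)²)`. The multivariable genetic
covariance matrix S is assembled from the pairwise fits over a shared SNP
alignment and block partition; V is the jackknife covariance of the
half-vectorized S (row-major lower triangle including the diagonal), made
PSD by eigenvalue clipping when needed (flagged). rg estimates beyond ±1
are reported as-is with a flag, never truncated.

**Factor models.** EFA is principal-axis factoring with iterated
communalities (SMC start, 1e-6 tolerance, error with the last delta on
non-convergence). Oblique rotation is oblimin (gamma = 0, gradient
projection started from the varimax orientation — the identity start can
sit on a saddle for symmetric block structures) or promax (kappa = 4).
Factor retention combines parallel analysis (95th-percentile eigenvalues
of uncorrelated normal data, counting the leading run) with the joint
rule: stop when an extra factor improves RMSEA by < 0.015 and total R² by
< 0.05.

CFA minimizes the diagonally weighted least squares discrepancy
`sum (r_ij - sigma_ij)² / Var(r_ij)` over the unique off-diagonal
correlations, with residual variances derived as 1 − communality so the
implied diagonal is exactly 1. Element variances come from tetrachoric
standard errors (phenotypic level) or the jackknife V after
standardization (genetic level; off-diagonals rescaled by `1/(S_ii S_jj)`,
a delta-method step that ignores the sampling error of the diagonal).
Model shapes: correlated first-order factors, a single general factor, a
second-order factor (first-order correlations implied as
`gamma gamma' + diag(1-gamma²)`), and a bifactor model (orthogonal general
+ specifics, with 2-indicator specific loadings equality-constrained — the
standard Heywood remedy). Optimization is L-BFGS-B with a polish restart;
parameter SEs are sandwich estimates using the full V when available. Fit
indices: chi² is the minimized discrepancy (weights are inverse sampling
variances, so this is approximate — the diagonal-weight convention); CFI
against the zero-correlation baseline on the same weights;
`RMSEA = sqrt(max(chi²-df,0)/(df(n-1)))` with n the smallest pairwise
count (phenotypic) or smallest per-trait regression N (genetic);
SRMR is the RMS correlation residual. Factor signs follow the
largest-|loading| indicator. Heywood cases (communality > 1) are flagged,
never silently truncated. Note that CFI carries a one-df penalty: freeing
a useless parameter can lower CFI even though the discrepancy never
increases.

**Latent-factor SNP association and heterogeneity.** With measurement
parameters fixed at the no-SNP solution, the common-pathway model is
linear in the SNP→factor path, so the estimate, its SE, and Q_SNP — the
fit decrement against the saturated independent-pathways model — are
closed-form GLS quantities; `Q ~ chi²(m-1)` for a simple-structure factor
with m indicators (single-indicator factors are rejected). The error
covariance of the SNP–indicator covariances combines the per-indicator
GWAS standard errors with a cross-trait error-correlation matrix. By
default that matrix is the normalized LDSC cross-trait intercepts (the
genomic-SEM convention); at M = 2,000 regression SNPs those intercepts
carry standard errors near 0.5 and destroy Q calibration, so the pipeline
supplies the observed phenotypic correlation of the outcomes instead —
under complete sample overlap the two estimate the same quantity, and the
sample correlation is precise. With this choice the mean Q_SNP under
common-pathway generation sits within a few percent of its df across
seeds. Q_Trait applies the same decrement logic to an external trait's
genetic correlations, with the sampling covariance taken from the
jackknife V. Factor effective N is the mean of `1/(2 MAF (1-MAF) SE²)`
over SNPs with MAF in [0.10, 0.40]; factor-GWAS output uses the sumstats
dialect plus QCHISQ/QDF/QP columns; loci are greedy distance merges of
genome-wide-significant SNPs within 250 kb.

**Disparity.** `D = r_p - r_g` elementwise (positive when the phenotypic
correlation is larger). The permutation test operates per condition on the
off-diagonal D row (signed by default; |D| available), shuffling the
covariate vector 1,000 times; the two-sided empirical p is
`(1 + #{|r_null| >= |r_obs|})/(n_perm + 1)`, which cannot reach zero.
Matrix-level similarity and the |D|-versus-SE technical correlation use
the unique off-diagonal pairs.

**Polygenic indices.** Weights are blockwise-ridge shrunk marginal
effects, `w = (R_block + lambda I)^-1 b` with `b = Z/sqrt(N)` — a
deterministic shrinkage filling the role Bayesian summary-statistic
methods play in PGI pipelines. Scores are allele-dosage weighted sums; a
configurable major-histocompatibility-complex interval (default
chr6:26–34 Mb on the simulated coordinate system) can be zeroed per
factor. Scores are residualized on birth year, sex, and principal
components and re-standardized. Latent-factor prediction fixes the
measurement loadings at a fitted solution and identifies the PGI→factor
paths from the polyserial correlations between scores and binary
indicators by least squares on the moment conditions
`cov(PGI_m, ind_i) = sum_f lambda_if (C gamma_f)_m`; R² per factor is
`gamma' C gamma`. Incremental R² compares a joint domain-PGI model with a
single general-factor PGI on the same holdout. Outcome regressions use the
demographic template age, sex, age², sex×age, sex×age².

## Pipeline and reproducibility

The runner follows the analysis order: simulate → GWAS (discovery sample)
→ munge → LD scores → multivariable LDSC → tetrachoric matrices (training
half for EFA, test half for CFA) → genetic EFA on odd chromosomes, CFA on
even → cross-level transfers → disparity + permutation → factor GWAS with
Q_SNP → PGIs scored in a holdout disjoint from the GWAS individuals.
Every stochastic stage draws its seed from the master seed by stable
hashing, so stages are independently reproducible and a rerun with the
same seed is byte-identical; outputs carry a config-hash header.
Coordinates are 1-based inclusive throughout.

## Scale, and what passing tests show

Default problem sizes (n = 20,000–50,000 individuals, M = 800–2,000 SNPs,
k = 4–10 conditions) were chosen so that the full validation battery runs
on a laptop while every estimator operates in its intended regime:
mean GWAS chi² of 1.5–6, LD scores spanning 1–7, tetrachoric standard
errors below 0.02. At M in the thousands, LDSC sampling noise per genetic
correlation is ~0.1 — orders of magnitude larger than at genome scale — so
recovery checks are phrased as coverage of jackknife intervals, and
element-wise precision claims are made only for quantities (tetrachoric
matrices, CFA loadings, injected disparities) whose error at these scales
is genuinely small. Passing tests demonstrate correctness and calibration
of the estimators under the generating model's assumptions; they do not
demonstrate robustness to stratification, relatedness, ascertainment, or
model misspecification, none of which are generated.

## Known limitations

* DWLS fit statistics use diagonal weights; chi² is only approximately
  chi²-distributed when moment errors correlate strongly.
* The genetic-level CFA ignores sampling error in the h2 diagonal when
  standardizing S (delta-method shortcut).
* The polyserial step in PGI prediction uses the two-step approximation
  `r_ps = r_pb sqrt(p(1-p))/phi(tau)`, which degrades for very rare
  conditions.
* `decouple_levels` represents the environmental structure through its
  Cholesky factor, so the re-targeted model no longer exposes a named
  environmental factor pattern.
* The permutation test treats condition rows separately and applies no
  multiplicity correction (by design, mirroring per-condition reporting).
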