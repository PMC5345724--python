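# Methods

## Model and reconstruction identity

The package treats a GWAS as a per-locus multiple linear regression of a
quantitative phenotype y on an allele-count genotype x and m candidate
covariates z_1..z_m. With centered variables the least-squares normal
equations involve only second moments, so the whole fit is a function of the
covariance matrix Φ of [y, x, z_1..z_m] (denominator n − 1 throughout) and
of n. The implementation computes, for predictor subset [x, z_s]:

- Ω: Φ restricted to the predictor rows/columns;
- Λ = diag(Ω) and b̂ = marginal coefficients σ_{y,v}/σ_v², so that
  Λ b̂ is simply the vector of predictor–phenotype covariances;
- β̂ = Ω⁻¹ Λ b̂, and cov(β̂) = ((σ_y² − β̂′Λb̂)/df) · Ω⁻¹.

Working on the covariance scale rather than the cross-product scale is
immaterial: the n − 1 denominators cancel between Ω⁻¹ and the residual
variance term. What must hold — and does — is that encoder, reader and
writer all use the same denominator.

Assumptions inherited from the linear model: a single shared n per locus
record, additive allele coding, homoskedastic residuals. Linear mixed
models, generalized linear models and interaction terms are out of scope.

## Degrees of freedom

Two conventions are offered because the reconstruction identity leaves the
df of the residual-variance estimate open for a centered regression with k
covariates:

- `centered` (default): df = n − k − 1, the literal form of the variance
  expression above;
- `ols`: df = n − k − 2, matching a with-intercept ordinary least squares
  fit (the convention statsmodels and R use).

The standard errors differ by sqrt((n−k−1)/(n−k−2)) — about 0.25% at
n = 200 and invisible at cohort sizes — but a test oracle must pick one;
the suite verifies exact agreement with individual-level OLS under `ols`
and the exact sqrt-ratio relation between the two.

## Numerical choices

- Ω is solved by Cholesky factorization with a pivoted-LU fallback; an
  explicit inverse is formed only for the covariance diagonal. A subset is
  declared collinear when Ω's reciprocal condition number (smallest/largest
  eigenvalue) falls below 1e-12 — small enough to pass benign scaling,
  large enough to catch duplicated covariates.
- A numerically negative residual variance (possible when Φ comes from
  rounded or inconsistent sources) is clamped at zero and the fit flagged
  degenerate rather than erroring.
- p-values come from the t distribution (finite-sample least squares), are
  computed from the log-scale survival function and reported as −log10 p,
  so |t| = 50 yields a finite value instead of underflowing to zero.
- Genome-wide scans batch the per-locus (k+1)×(k+1) solves into stacked
  LAPACK calls; the scalar kernel is the reference implementation and the
  suite checks the two agree to machine precision.
- Missing genotypes are mean-imputed per locus before encoding, keeping one
  shared n for the generic block and all loci; rows with missing phenotype
  or covariates are dropped globally first. Mean imputation is this
  package's choice for keeping Φ internally consistent, not a claim about
  how any particular dataset was processed.
- Eigenvector signs are fixed by making each column's largest-magnitude
  entry positive, so covariate matrices are reproducible across runs and
  BLAS builds. With a degenerate spectrum the chosen basis is arbitrary but
  still orthonormal.

## Scanning, enumeration and hit evaluation

λ_GC is the median of the per-locus 1-df association statistics divided by
the χ²₁ median (0.4549…); the statistic used is the squared SNP t, which at
GWAS degrees of freedom is χ²₁ beyond reporting precision.
Genomic-control adjustment divides t² by λ_GC and recomputes p from the
χ²₁ tail; it is applied only when λ_GC > 1 (deflation-only, the standard
practice — the inflation-factor logic has no agreed λ_GC < 1 counterpart).

Subset enumeration is guarded at m ≤ 20 and streams one locus at a time.
Hit calling uses a strict inequality against −log10(alpha/n_tests); for
enumeration input a locus is a hit when *any* of its 2^m models clears the
line. A combined threshold over n_models models and n_traits traits is the
direct Bonferroni form −log10(alpha/(n_tests · n_models · n_traits)).

In-depth evaluation sorts a locus's −log10 p values ascending and starts a
new group exactly where a neighbouring gap exceeds 1.0 (a gap of exactly
1.0 stays in-group; the gap is configurable). Group separation is measured
by a one-way ANOVA F with p from F(g−1, N−g); a single group or zero total
variance reports not-applicable (NaN), and perfect separation reports an
infinite-F sentinel rather than an arbitrary large number.

## Meta-analysis

Cohort records are intersected by SNP id and aligned to the first cohort's
allele pair: identical pairs pass, swapped pairs flip the genotype coding
(negating the covariances, complementing the frequency), anything else is
excluded with reason "allele-mismatch" — strand flips are deliberately not
inferred, and palindromic A/T and C/G variants are aligned by labels only
with a warning. Pooling is inverse-variance fixed effects
(w = 1/se², pooled se = (Σw)^(−1/2)) with a normal reference for the pooled
z (cohort dfs are large and unequal); Cochran's Q is available as an
optional heterogeneity diagnostic but no random-effects model is
implemented. Covariates are cohort-local: subset {1,3} means each cohort's
own first and third eigenvectors, which is the intended semantics for
ancestry covariates and the reason subset switching needs no re-export.

## Synthetic data: what it emulates and what it does not

The generator exists so every pipeline stage is testable without any
download. It produces independent biallelic loci with ancestral frequencies
uniform on the configured MAF range, Balding–Nichols subpopulation
frequencies at a given Fst (the minimal standard model that makes GRM
eigenvector covariates meaningful), binomial genotypes (or doubled haploid
draws for inbred panels), and strictly additive phenotypes in which each
causal locus contributes a fixed fraction of unit total variance through
its standardized genotype.

Default study designs mirror the demonstrations the method is known by: a
295-sample panel with five GRM-eigenvector covariates for the
reproduction-fidelity check, and two cohorts of 3191 and 2309 samples
sharing 9124 loci with one causal locus at 5% variance explained for the
meta-analysis check (run at full size; the suite's smaller variants keep
unit tests fast). Mild two-subpopulation structure (Fst 0.05 for the single
panel, 0.01 across the cohorts) is this package's choice where the original
designs state none.

What the generator does **not** emulate: linkage disequilibrium,
genotyping error, admixture gradients beyond discrete subpopulations,
non-additive architecture, case/control traits. Passing tests therefore
demonstrate algebraic and statistical correctness of the reconstruction and
pooling machinery, not robustness to the correlational structure of real
panels — though the reconstruction identity itself is exact for any data.

## Bundled fixture

`worked_example_phi()` returns the 5×5 covariance matrix of a published
single-locus demonstration (null locus, MAF 0.23, three N(0,1) covariates,
n = 200). The entries are a display-rounded rendering of that sample, and
the rounding is internally inconsistent at the third decimal (the printed
first marginal coefficient −0.0143 differs from −0.005/0.338 ≈ −0.0148
computed from the printed matrix). Checks against the printed values
therefore use display-rounding tolerances (2e-3 on coefficients); exact
assertions are reserved for internally regenerated data.

## Known limitations

- The NSS encoding assumes one shared sample set per study; per-locus
  sample sizes (as arise from per-marker missingness filters in some
  pipelines) are only approximated through mean imputation.
- λ_GC from t² assumes large residual df; at very small n the χ²₁
  approximation is visibly conservative.
- The homozygosity QC statistic counts non-integer dosages as
  heterozygous, making the inbred-panel filter meaningful for hard calls
  only.
- Fixed-effects pooling assumes a common true effect; heterogeneous
  cohorts will produce well-defined but uninterpretable pooled estimates
  (inspect Cochran's Q).
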