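# Methods

This note documents the models implemented in `famscan`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic-data
generator does and does not emulate.

## The family design and the liability-threshold model

The target design is a population register of nuclear families: singletons,
childless spouse couples, and sibships of size 1–6 with 0, 1 or 2 parents
genotyped. The binary trait ("ever/never" initiation) is modelled as the
exceedance of a latent standard-normal liability:

    L_i = β (g_i − 2p) + ε_i,         y_i = 1{L_i > z}

* `g_i ∈ {0,1,2}` is the dosage at a causal locus with allele frequency
  `p`; `β = √(q²/2p(1−p))` fixes the locus's share of the liability
  variance at `q²`.
* `ε` is multivariate normal within a family with variance `1 − q²` and
  correlations `r_spouse = 0.39`, `r_sib = 0.35`, `r_po = 0.15`. These are
  the empirical relative-pair correlations of the motivating register
  sample and are applied to the **residual** liability; at `q² ≤ 0.015`
  the genotype's contribution to relative-pair correlations (≤ 0.0075 for
  siblings) is below the precision at which such correlations are
  reported, so total and residual parameterizations are interchangeable
  in practice.
* `z = 0.85`, giving prevalence `1 − Φ(0.85) = 0.1977 ≈ 20%`.

Within a family, liabilities are drawn via the Cholesky factor of the
configuration's correlation matrix; a non-positive-definite configuration
(possible with user-supplied negative correlations) is rejected with the
configuration named.

Mendelian transmission is implemented for the causal locus: founder
genotypes are Binomial(2, p); each parent transmits an allele with
probability g/2. For sibships without genotyped parents, parental
genotypes are synthesized, used for transmission, and discarded — this
makes the sibling dosage correlation exactly 1/2, which matters because
the GEE's clustering assumption presumes real within-family genotype
correlation.

### Family-configuration mixture

The register publishes the family count (3690 in the power design) and
the analyzed individual count (~6,700) but not the configuration mixture.
The default mixture (52% singletons, 18% couples, the rest sibships of
1–6 with 0–2 parents) was fixed once so that 3690 families carry ≈6,725
individuals in expectation, on the grounds that power depends mainly on
the total and effective sample size rather than on the exact mixture. It
is a `FamilyMixture` config entry (`"<n_sibs>+<n_parents>"` keys in the
YAML config).

### Defaults of the liability model

`LiabilityParams.q2` defaults to **0** (a null generator): effect sizes
are an analysis choice, always passed explicitly (the power engine uses
q² = 0.01/0.015), and a null default makes the generator's calibration
properties — prevalence `1 − Φ(0.85)`, spouse/sib/parent-offspring
correlations exactly 0.39/0.35/0.15 — hold without attenuation.

## Censored age at onset

No generative onset model is published for this design; the package's own
choice is a Weibull proportional-hazards model,

    S(t | η) = exp(−(t/λ)^k · e^η),      η = β_g (g − 2p) + γ ε,

with shape `k = 2.5`, scale `λ = 104` years, `β_g = 0` by default, and
frailty loading `γ = 0.5` on the liability residual so that early onset
co-segregates within families consistently with the binary trait.
Observation (censoring) ages are normal (mean 47, SD 17.5 years,
truncated at 16), matching the register's survival-cohort age
distribution. An individual is an event when the latent onset does not
exceed the observation age; within the survival cohort the initiation
indicator is *defined* as the event indicator. Latent onsets ≤ 10 years
are treated as unreliable reports and excluded, mirroring the register's
"older than 10 years" inclusion rule.

The scale λ = 104 was calibrated once, by simulating 55,000 individuals
under the default censoring scheme and choosing the scale whose event
fraction matches the register's 16.6%; the frozen default reproduces
16.5% at that size and stays within ±1.5 points at cohort size ~5,000.

## Logistic GEE with exchangeable working correlation

Per SNP, the binary trait is regressed on allele dosage (additive coding)
and covariates by generalized estimating equations with logit link. The
working correlation is exchangeable — one correlation α common to all
family-member pairs — estimated each iteration by the moment estimator on
Pearson residuals with a degrees-of-freedom-corrected denominator
(Σ cluster pairs − p). Fisher scoring iterates to a relative parameter
change below 1e-8 (max 50 iterations). The reported covariance is the
Liang–Zeger sandwich M⁻¹BM⁻¹ with B the sum of per-family score outer
products; two-sided Wald p-values use the normal reference.

Numerical notes: clusters are batched by size (sizes 1–8 in this design),
with the exchangeable inverse applied analytically as
R⁻¹ = c₁I + c₂J; α is clamped inside (−1/(s_max−1), 0.99); an
all-singleton dataset fixes α = 0 with a log note; a diverging linear
predictor (|Xβ| > 30) flags possible separation. With singleton clusters
the fit reduces *exactly* to logistic maximum likelihood with HC0 robust
errors, which is verified against statsmodels in the test suite, as is
the clustered fit against statsmodels' GEE.

## Cox proportional-hazards scan

Age at onset (onset age for events, observation age for censored rows) is
analyzed by Cox partial likelihood, maximized by Newton iteration with
step halving. Breslow tie handling is the default — onset ages reported
in whole years make ties routine — with Efron available
(`CoxPH(ties="efron")`). Robust covariance aggregates Breslow-form score
residuals within families before forming the sandwich. Monotone
likelihoods (separation) are flagged and the coefficient capped at ±20;
zero-contrast columns get coefficient exactly 0. Time enters at age scale
with entry at 0 — no left truncation, as the design censors at "last
seen" without delayed-entry bookkeeping. The implementation is verified
against a brute-force partial-likelihood oracle on 4-subject toys and
against lifelines' cluster-robust fit.

## GATES gene-based test

SNPs are assigned to a gene when their position falls within
[start − 5 kb, end + 5 kb] (1-based inclusive coordinates everywhere); a
SNP may serve several overlapping genes. With sorted p-values
p₍₁₎ ≤ … ≤ p₍ₘ₎,

    P_gene = min_j  m_e · p₍ⱼ₎ / m_e(j),

where m_e is the effective number of tests of the full SNP set and m_e(j)
that of the top-j subset, both computed as m − Σ(λᵢ − 1) over eigenvalues
λᵢ > 1 of the SNP **p-value** correlation matrix. Genotype LD r is mapped
to p-value correlation by the sixth-order polynomial published with the
test (a ρ = r² fallback is a config switch). SNPs carry equal weights.
LD can be restricted to founders (`ld_individuals=`) to avoid
family-induced inflation of r. The significance threshold divides the
base α = 0.01 by the number of genes actually tested and is logged —
published accounts of this pipeline print slightly inconsistent gene
counts, so the realized count is authoritative here.

## GREML

* **GRM**: A_jk = (1/m) Σᵢ (x_ij − 2pᵢ)(x_ik − 2pᵢ)/(2pᵢ(1−pᵢ)), with
  allele frequencies recomputed in the analyzed sample (the convention of
  the standard GREML tooling); monomorphic SNPs are skipped. Written as
  GCTA-compatible gzipped triplets plus an id file.
* **Pruning**: off-diagonal relatedness above 0.025 is resolved greedily —
  repeatedly drop the individual with the most over-cutoff partners, ties
  broken by id order. The reference tooling's exact removal order is
  unspecified, so determinism and logging take priority.
* **REML**: V = Σ_c A_c σ²_c + I σ²_e maximized by average-information
  updates with an EM first step and step halving, variances floored at
  1e-8·Var(y) (boundary hits reported as exact zeros and logged);
  standard errors from the inverse AI matrix; h² = σ²_g/Σσ² with
  delta-method SE. Convergence: max parameter change < 1e-6·Var(y).
* **Boundary LRT**: a variance tested on its zero boundary is referred to
  the 50:50 mixture of a point mass and χ²₁, i.e. p = ½·P(χ²₁ > LRT).
  This mixture reproduces the published worked value (LRT = 8.60 →
  P = 0.0017, printed truncated as 0.0016), which a plain χ²₁ does not.
* **Scale conversion**: a 0/1 phenotype is analyzed on the observed scale;
  the liability transformation h²_liab = h²_obs·K(1−K)/φ(Φ⁻¹(1−K))²
  (default K = 0.22) is a reporting step only — no ascertainment
  correction, as the sample is population-based.
* **Chromosome-length regression**: OLS of per-chromosome variance
  fractions on length, one-tailed p for a positive slope on n−2 df.

## Genomic control and concordance

λ is the median association χ² over 0.45494 (the χ²₁ median); a mean-based
λ is behind a flag. Correction divides χ² by λ (λ < 1 applies none, logged)
and preserves p-value order. LD pruning keeps, greedily, the remaining SNP
with the smallest p and removes everything with r² above the ceiling
(default 0.1) against it. Sign concordance between two studies uses the
exact binomial test against 1/2; the default two-sided method sums point
probabilities ≤ the observed one (scipy's convention), with a doubled-tail
option — the two differ on asymmetric toys and the choice is logged.

## Monte-Carlo power

Each replicate draws causal genotypes and liabilities on a fixed family
structure (resampling structures per replicate is a flag; power is
insensitive to it since it depends on the structure only through the
cluster-size distribution), fits the intercept + dosage GEE, and records
the sandwich Wald p-value. Power is significant/converged replicates;
non-converged replicates are excluded from the denominator (a recorded
choice; >5% failures raises a warning). Replicate RNGs derive from
(master seed, replicate index), making runs reproducible and splittable.
The desk default is 1,000 replicates (binomial SE ≈ 1.6 points near 45%
power); the published design used 10,000, reachable by config.

## What the generator does not emulate

* Null ("background") SNPs are drawn from a Gaussian copula with AR(1)
  within-block latent correlation, independently across individuals — they
  carry LD but **no family transmission** (only the causal locus does).
  Type-I calibration of the scans is unaffected (a genotype independent of
  the trait cannot confound), but GRMs built from these SNPs do not encode
  pedigree relatedness.
* Copula LD attenuates on the dosage scale, increasingly for low-MAF SNPs;
  the block correlation parameter is the latent, not the realized, r.
* No population stratification, assortative-mating dynamics, monozygotic
  twins (the motivating analyses excluded them), X/Y/MT chromosomes,
  dosage (non-integer) genotypes, or missing genotypes — best-guess
  post-imputation data are complete by construction.
* Covariates (sex, age, birth-cohort dummies, 3 PCs, batch) are
  exchangeable noise: they exercise the covariate code paths but carry no
  confounding. Passing tests therefore demonstrate correctness of the
  estimators under the stated model, not robustness to real-data artifacts.

## Problem sizes used in the checks

The test suite and the acceptance script use desk-scale sizes chosen to
keep Monte-Carlo error well inside each tolerance: 1,000 power replicates
per effect size; 100,000 individuals for the prevalence check; 50,000
pairs per correlation check; n = 2,000 × m = 5,000 for GREML recovery
(reported SE ≈ 5 points); ~5,000 individuals for the survival-cohort
calibration; 150–250 null SNPs for scan-calibration KS checks.
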