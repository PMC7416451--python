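# Methods

`gravimet` implements an integrated analysis of maternal insulin
sensitivity in pregnancy for multi-ancestry OGTT cohorts with paired
metabolomics and genotype data, together with a synthetic cohort
generator that reproduces the statistical structure such studies rely
on. This note documents the models, the generator, the numerical
choices, and what passing tests do and do not establish.

## The insulin-sensitivity index

Insulin sensitivity is summarised per subject by a scaled composite of
OGTT glucose and C-peptide measurements,

    IS = 1000 / sqrt(FPG × FCP × G × C),

with FPG, FCP the fasting plasma glucose (mmol/l) and C-peptide (μg/l)
and G, C the means of the fasting and 1 h values. The index is
dimensionless up to the scaling constant, strictly decreasing in each
component, and homogeneous of degree −2 (doubling all four inputs
quarters it). Units are trusted as given; no conversion layer is
applied. Downstream stages analyse the index on the natural or the
natural-log scale — the choice is a configuration switch
(`use_log_index`, default on), because per-allele effect sizes near
−0.2 are only interpretable on a log-like scale while the index itself
is right-skewed.

## Synthetic cohort generator

The generator emulates a four-stratum ancestry design: per stratum,
`n_genotyped_per_stratum` (default 1100) genotyped subjects of whom the
first `n_per_stratum` (default 400) also carry the metabolomics panel,
mirroring the partial overlap typical of such studies. Components:

- **Genotypes.** Biallelic SNP dosages drawn under Hardy–Weinberg
  within stratum. Per-SNP base frequencies are uniform on (0.10, 0.90)
  with per-stratum perturbations (SD 0.05) so that genotype PCs carry
  ancestry information. One focal SNP has exact per-stratum
  frequencies from the configuration (defaults 0.15/0.40/0.35/0.50).
- **Covariates.** Age ~ N(29, 5²) truncated ≥ 18 years, BMI ~ N(27, 5²)
  truncated > 15 kg/m², height ~ N(160, 7²) cm, gestational age ~
  N(27.7, 1.6²) weeks, parity ~ Poisson(1), smoking/alcohol ~
  Bernoulli(0.10/0.15), storage time uniform 1–6 weeks, blood pressure
  with mean arterial pressure (SBP + 2·DBP)/3. Only the Northern
  European stratum is multi-centre (three field centres); each other
  stratum has one centre, so field-centre indicators encode ancestry.
- **Mediation triangle.** The latent log index is
  `stratum intercept + c·dosage + b·mediator + covariate effects +
  noise` and the mediator metabolite is `a·dosage + covariate effect +
  noise`, so the implied proportion mediated is a·b/(a·b + c). Default
  paths a = −0.19, b = 0.16, c = −0.19 give a proportion mediated of
  13.8%. The mediator defaults to a fully observed targeted-arm
  metabolite at the 1 h timepoint: a censored mediator would make
  complete-case mediation biased by construction, which is a property
  of censoring, not of the mediation machinery under test.
- **Metabolites.** 135 metabolites (64 targeted/clinical, 71
  non-targeted) at two timepoints, unit variance with within-class
  equicorrelation 0.30 (a shared class factor), stratum-specific means
  (SD 0.3) and a 1 h shift. Raw-scale encoding exercises the transform
  stage: non-targeted values are 2^(latent+18) peak areas,
  acylcarnitines exp(latent), other targeted metabolites the latent
  value itself. Non-targeted metabolites are left-censored at the
  configured per-metabolite quantile (default 0.30): a cell is missing
  if and only if its value falls below that metabolite's empirical
  detection limit. Daily batches of 22 samples carry an additive shift
  (SD 0.15 on the log2 scale) on non-targeted features only — targeted
  isotope-dilution assays are treated as batch-stable.
- **OGTT inversion.** OGTT values are generated backwards: fasting
  glucose ~ lognormal(ln 4.5, 0.1) and fasting C-peptide ~
  lognormal(ln 1.7, 0.25) are drawn, and the 1 h values are solved with
  a single multiplicative inflation factor r applied to both, under
  which the index reduces to 2000/(FPG·FCP·(1+r)). Solving for r makes
  the realised index equal the latent target exactly (round-trip
  relative error < 1e-10), so the index stage is exercised on exactly
  the structure the formula assumes without modelling OGTT physiology.
  Draws implying r ≤ 0 are rejected and redrawn jointly with the index
  noise; rare subjects whose acceptance region is very small get their
  noise drawn from its exact truncated conditional. Rejections are
  counted in the ground-truth record; the truncation affects a
  ~3·10⁻⁴-probability tail for the most extreme subject observed and
  is ignored.

One `SeedSequence` per cohort is spawned into named substreams in a
fixed order (genotypes, covariates, OGTT, metabolites, batches), so
enlarging the metabolite panel does not perturb the genotypes.

What the generator does **not** emulate: linkage disequilibrium
(SNPs are independent), population-genetic ancestry (strata are labels
with different frequencies and intercepts), OGTT curve physiology,
assay drift within batch, and correlated missingness across
metabolites. Passing tests therefore establish correctness of the
statistical machinery under the stated generative model, not robustness
to those real-data features.

## Preprocessing

Transforms are class-specific: natural log for acylcarnitines and
3-hydroxybutyrate, log2 for non-targeted peak areas, pass-through
otherwise; the transform state is recorded and double-transforming
rejected. Batch centring subtracts the per-batch median and restores
the grand median (a deliberate simplification of QC-pool mixture-model
batch correction, which is out of scope); the pipeline applies it to
the non-targeted arm only. The outlier screen masks cells ≥ 5 SDs from
the per-metabolite mean (computed over observed cells, single pass, not
iterated), and subjects with strictly more than 10 outlying metabolites
are excluded — "≥" and "strictly more" are deliberate boundary
readings. Pipeline order is transform → batch-centre → mask → exclude;
the order is fixed by configuration and was an open choice.

## Association models

Four nested covariate models are supported: model 1 = {mean arterial
pressure, age, gestational age, field centre, newborn sex, storage
time}; model 2 adds BMI; model 3 adds parity; model 4 adds both.

Fully observed metabolites use OLS with the index as outcome and the
metabolite as exposure. Censored non-targeted metabolites use a
two-part ("mixture") likelihood with the metabolite as outcome and the
index as predictor:

    Σ_observed [ln π_i + ln N(y_i; x_i'β, σ²)] + Σ_censored ln(1 − π_i),
    logit(π_i) = x_i'γ,

maximised jointly by L-BFGS with analytic gradients, initialised from
complete-case OLS and an intercept-only logistic, with up to five
jittered restarts. The likelihood is separable in (β, σ) and γ, so the
joint optimum coincides with logistic regression on presence plus OLS
on observed cells; at zero censoring the logistic part saturates and is
dropped, and β equals full-data OLS exactly. Standard errors for
mixture β come from subject-level nonparametric bootstrap (B
configurable, ≥ 50; failed replicates dropped and counted, > 20%
failures is an error); the analytic observed-cell OLS SE is attached as
the default. Note the two-part model treats presence as logistic given
the design — under the generator's true detection-limit mechanism it is
a *working* model (as it is for real GC-MS data) and its β is somewhat
attenuated relative to the latent uncensored effect.

Delta (1 h − fasting) analyses use OLS complete cases for all arms:
differencing destroys the left-censoring structure the two-part
likelihood assumes.

BH-FDR is applied within each (timepoint × model) family across
metabolites; q < 0.05 flags significance.

## Meta-analysis

Per-stratum estimates are pooled with DerSimonian–Laird random effects
(REML optional): Q = Σ w_i (β_i − β_FE)², τ̂² = max(0, (Q − (k−1)) /
(Σw − Σw²/Σw)), weights 1/(se² + τ̂²), two-sided normal p. Q is tested
against χ²(k−1). Two I² forms are reported — the τ²-based form with the
typical within-stratum variance, and the Higgins form
100·max(0, (Q−df)/Q) — both zero whenever Q ≤ k−1. GWAS pooling is
fixed-effects, inverse-variance by default with a sample-size-weighted
z-score scheme selectable (under which the p-value comes from the
pooled z while the reported β/SE remain inverse-variance, since a
z-scheme carries no effect scale).

`verify_table1` re-derives the heterogeneity columns of the worked
example table embedded as a fixture: every printed Q-test p-value is
reproduced to 4 decimals from the printed Q with k = 4, and all rows
with Q < 3 have DL τ̂² = 0 and hence I² = 0, as printed. Printed I²
values for rows with Q > 3 derive from unpublished within-stratum
variances and are not re-derivable from Q alone; they are not chased.

## Networks

Metabolites are residualised on confounders (per-metabolite OLS,
complete cases, standardised residuals); the residual covariance is
estimated pairwise-complete (censored cells excluded per pair) and
projected to the PSD cone by eigenvalue clipping at 1e-8 when needed.
The graphical lasso (λ default 0.1 on standardised residuals; the
unpenalised λ = 0 limit computed as a direct inverse) yields the sparse
precision matrix whose nonzero off-diagonal entries define
conditional-dependence edges with partial correlations
ρ_ij = −Θ_ij/√(Θ_ii Θ_jj). The exported sub-network keeps significant
metabolites plus their direct neighbours.

Communities minimise the Potts Hamiltonian
H(σ) = −Σ_{i<j} (A_ij − γ·k_i k_j/2m) δ(σ_i, σ_j) (configuration null,
resolution γ = 1). Components of ≤ 6 nodes are solved exactly by set-
partition enumeration — the annealing heuristic is unreliable and can
stall on tiny graphs — and larger components use igraph's spinglass
annealer (start T = 1, cooling 0.99, stop T = 0.01, ≤ 25 spins) with 5
restarts, keeping the lowest-Hamiltonian partition; a single run misses
the planted optimum in roughly a quarter of seeds. All runs are
seed-reproducible.

A caution on the graphical lasso: when adjacent edges are strong
(summed adjacent covariances exceeding the hub variance), the penalty
on those edges forces a compensating spurious edge between their
endpoints, so exact-zero recovery of a conditional independence is only
guaranteed for moderate partial correlations.

## GWAS

Per stratum: MAF filter (minor-allele frequency < 0.01 dropped,
boundary kept inclusively), genotype PCs from column-standardised
dosages via SVD (two by default; deterministic sign convention), then a
vectorised additive-model scan by Frisch–Waugh residualisation — per-SNP
β, SE, t-based p and partial R² agree exactly with a joint OLS refit.
Variance explained is 100·(R²_full − R²_cov)/(1 − R²_cov), the squared
partial correlation. Allele codings are harmonised across strata by
flip-and-negate before pooling; genome-wide significance is flagged at
5×10⁻⁸ and SNP–metabolite Bonferroni significance at 0.05/135.

## Mediation

With all-linear paths and shared covariates, the structural-equation
estimates equal a two-regression decomposition: mediator ~ snp +
covariates gives a; outcome ~ snp + mediator + covariates gives b and
the direct effect c; indirect = a·b; total = a·b + c, asserted on every
fit against an independent reduced regression (outcome ~ snp +
covariates) to float tolerance. SE(indirect) is the Sobel delta formula
√(a²se_b² + b²se_a²); the proportion mediated indirect/total gets
percentile-bootstrap CIs (B ≥ 200; replicates with |total| below a
floor excluded from the ratio CI and counted) because ratio
distributions are non-normal. Classification: "mediation" if the
indirect CI excludes 0 and indirect and total share sign; "suppression"
if the CI excludes 0, |direct| > |total| and the signs oppose
(the proportion mediated is not meaningful there); otherwise "none".

In the pipeline, mediation adjusts for field centre (which encodes
stratum), genotype PCs and the standard covariates. The plasma-glucose
adjustment used on real data is off by default on synthetic cohorts
(`mediation_adjust_glucose`): because the generator solves OGTT glucose
from the index, 1 h glucose is an arithmetic descendant of the outcome
there, and conditioning on it would condition on the outcome itself.

## Problem sizes and tolerances

The test suite exercises: the full pipeline at 4×100 metabolomics /
4×160 genotyped subjects; mixture-model self-consistency at n = 400
with 30% censoring over 200 replicates; end-to-end mediation recovery
at n = 2000 with planted proportion 0.30 over 200 replicates with
B = 400 bootstrap (mean within 3 Monte-Carlo SEs; 95% CI coverage
within 93–97%); spinglass exhaustive checks on ≤ 9 nodes and planted
3-block recovery over 20 seeds; null SNP scans of 250 SNPs × 40
replicates for test size. The acceptance script runs the pipeline at
the full study layout (4×400 metabolomics, 4×1100 genotyped, 135
metabolites). Numerical tolerances: index round-trip 1e-10 relative;
mixture/OLS equivalence 1e-6 relative; glasso λ=0 limit 1e-6; BH-FDR
exact against hand computation.

## Known limitations

- The two-part censored-metabolite model is a working model under true
  detection-limit censoring; no Tobit-style correction is attempted.
- No LD, kinship, imputation or mixed models in the GWAS; synthetic
  scans use small SNP panels.
- The network stage exports graphs; it does not render figures.
- Percentile bootstrap CIs for the proportion mediated are slightly
  conservative-to-nominal at n = 2000; no BCa correction is applied.
- The ratio estimator indirect/total carries O(1/n) finite-sample bias
  (empirically ≈ +0.001 at n = 2000 for a true proportion of 0.30).
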