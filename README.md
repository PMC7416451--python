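# gravimet

Integrated metabolomic and genetic analysis of maternal insulin
sensitivity in pregnancy.

Pregnancy induces a marked drop in maternal insulin sensitivity in the
second and third trimesters, and the mechanisms are incompletely
understood. Studies that profile pregnant cohorts combine a composite
insulin-sensitivity index from OGTT glucose and C-peptide, per-
metabolite regression (with special handling of left-censored
non-targeted metabolites), random-effects meta-analysis across ancestry
groups, partial-correlation metabolite networks, additive-model SNP
association, and mediation analysis asking how much of a SNP's effect
on insulin sensitivity flows through a metabolite. `gravimet`
implements that entire analysis chain as a tested, reusable library
with a thin CLI, exercised end-to-end on a synthetic multi-ancestry
cohort generator whose ground truth is known exactly. It is aimed at
statistical geneticists and metabolomics analysts who want the pipeline
on their own cohort data (TSV phenotype/metabolite tables, VCF or
dosage matrices), and at methodologists who want a fully controlled
simulation of this study design.

## The statistics at the core

**Insulin-sensitivity index.** Per subject,
`IS = 1000 / sqrt(FPG · FCP · G · C)` with fasting plasma glucose FPG
(mmol/l), fasting C-peptide FCP (μg/l) and G, C the means of the
fasting and 1 h glucose and C-peptide values.

**Censored-metabolite mixture model.** Non-targeted GC-MS metabolites
are missing below their detection limits. Each is modelled with a
two-part likelihood — logistic presence, normal log2 abundance when
present, shared design x (phenotype + covariates):

    ℓ(β, σ, γ) = Σ_obs [ln π_i + ln N(y_i; x_i'β, σ²)] + Σ_cens ln(1 − π_i),
    logit(π_i) = x_i'γ,

maximised jointly; bootstrap SEs for β.

**Random-effects meta-analysis.** Per-stratum estimates pool with
DerSimonian–Laird: Q = Σ w_i (β_i − β̄_FE)², τ̂² = max(0, (Q − df)/(Σw −
Σw²/Σw)), weights 1/(se_i² + τ̂²); heterogeneity reported as Q, its
χ²(k−1) p-value, and I². GWAS pooling is fixed-effects (inverse-
variance or sample-size-weighted z).

**Networks.** Graphical-lasso precision matrix on confounder-adjusted
residuals; edges are conditional dependencies with partial correlations
ρ_ij = −Θ_ij/√(Θ_ii Θ_jj); communities minimise the spinglass Potts
Hamiltonian H = −Σ_{i<j}(A_ij − γ k_i k_j/2m) δ(σ_i, σ_j).

**Mediation.** Product-of-coefficients with shared covariates:
a (SNP→metabolite), b (metabolite→index), c (direct); indirect = a·b,
total = a·b + c (an exact linear identity, asserted per fit), Sobel SE
for the indirect effect, percentile-bootstrap CI for the proportion
mediated a·b/(a·b + c), and a mediation/suppression/none
classification.

## Worked example

```python
from gravimet import (OGTTRecord, is_ogtt_cpep, SimulationConfig,
                      simulate_cohort, PipelineConfig, run_all)

# the index for one subject: fasting glucose 4.5 mmol/l, 1 h 7.4;
# fasting C-peptide 1.7 ug/l, 1 h 7.0
print(round(is_ogtt_cpep(OGTTRecord(fpg=4.5, g1h=7.4, fcp=1.7, cp1h=7.0)), 2))
# 71.06   (G = 5.95, C = 4.35; 1000/sqrt(4.5*1.7*5.95*4.35))

# a small synthetic cohort and the full pipeline
cfg = PipelineConfig(
    sim=SimulationConfig(n_per_stratum=120, n_genotyped_per_stratum=200,
                         n_snps=40, n_metabolites=30, n_nontargeted=12,
                         seed=11),
    mediation_B=300,
)
out, manifest = run_all(cfg)
m = out["mediation"]
print(round(m.a, 3), round(m.b, 3), round(m.c, 3),
      round(m.proportion_mediated, 3), m.classification)
# -0.168 0.149 -0.196 0.113 mediation
```

The generator planted the mediation triangle a = −0.19, b = 0.16,
c = −0.19 (implied proportion mediated 0.138); the fitted paths above
recover it from the simulated OGTT measurements, genotypes and the QC'd
metabolite panel, and the bootstrap CI classification calls it
mediation. `out["gwas"]["meta"]` holds the pooled per-SNP scan (the
focal SNP's pooled β ≈ −0.218 against a planted total effect of
−0.2204), and `out["meta"]` the per-metabolite random-effects pooling
with Q, its p-value, I² and BH-FDR q-values.

The same stages are scriptable from a shell:

```bash
gravimet simulate --out cohort/ --seed 7
gravimet index --in cohort/subjects.tsv --out indexed.tsv --log
gravimet run --config run.yaml --out results/
gravimet verify-table1
gravimet mediate --data cohort/ --mediator palmitoleic_acid --timepoint 1h \
    --bootstrap 1000 --seed 7 --out med.json
```

`gravimet verify-table1` re-derives the heterogeneity columns of the
published worked-example table from its printed Q statistics (k = 4
strata): each Q-test p-value reproduces to 4 decimals, and every row
with Q below its degrees of freedom has DerSimonian–Laird τ̂² = 0 and
hence I² = 0, as printed.

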