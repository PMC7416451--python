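# Example configuration for `gravimet run --config run.yaml --out DIR`.
# Any omitted field keeps its default; `sim` fields mirror SimulationConfig.
sim:
  n_per_stratum: 400          # metabolomics subjects per ancestry stratum
  n_genotyped_per_stratum: 1100
  n_metabolites: 135
  n_nontargeted: 71
  n_snps: 100
  path_a: -0.19               # SNP -> mediator (SD units per allele)
  path_b: 0.16                # mediator -> log insulin-sensitivity index
  path_c: -0.19               # direct SNP -> log index
  censor_quantile: 0.30       # detection-limit quantile, non-targeted arm
  seed: 1
models: [4]                   # covariate models to fit (1-4)
timepoints: [fasting, 1h, delta]
sd_cut: 5.0                   # outlier screen threshold (SDs)
max_outliers: 10              # subject exclusion threshold
lam: 0.1                      # graphical-lasso penalty
gamma: 1.0                    # spinglass resolution
n_pcs: 2
gwas_scheme: fixed_iv         # or fixed_samplesize
mediation_B: 1000
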