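divergence: 0.3
g_ridge: 1.0e-06
include_full_data: false
k_folds: 4
map_length_cm: 100.0
mcmc_burn_in: 20000
mcmc_cycles: 50000
mcmc_thin: 20
min_call_rate: 0.95
min_maf: 0.01
missing_rate: 0.0
models:
- blup
- gblup
- lasso
- mix4
n_chromosomes: 10
n_f0: 20
n_f1: 51
n_f2: 511
n_hatches: 4
n_qtl: 200
n_sires_f1: 8
n_snps: 5000
pi:
- 0.889
- 0.1
- 0.01
- 0.001
scenarios:
- family
- random
seed: 0
traits:
- BW6
- BW12
- EP
- BMP
- LMP
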