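# Default experiment grid: the eight standard scenarios.
#
# Scenarios cross a moderate (0.10) or low (0.05) control-arm outcome risk
# with a moderate (RR 0.75) or null (RR 1) treatment effect and a strong
# (RR 5) or moderate (RR 2) prognostic factor.  Prevalence grids follow the
# setting: 14 values in (0.005, 0.995) when the prognostic factor is
# sampled at random (unconditional), 11 values in (0.05, 0.95) when a 5%
# between-arm imbalance is imposed (conditional).
scenario_ids: [1, 2, 3, 4, 5, 6, 7, 8]
settings: [unconditional, conditional]
lambda_grid: null        # null -> per-setting default grid
n_grid: [25, 50, 125, 500, 1000, 2000]
n_replicates: 10000
d1_thresholds: [0.005, 0.01, 0.025, 0.05, 0.10, 0.15, 0.20]
d2_thresholds: [0.0, 0.05, 0.10, 0.15, 0.20, 0.25]
base_seed: 20120522
imbalance_method: exact
replicate_dump: false
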