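# Example simulator configuration for `seedtox simulate` / `seedtox all`.
# Any omitted field falls back to the SyntheticConfig default (the reference
# effect condition documented in docs/methods.md).
n_genes: 2000
utr_length_range: [200, 2000]
base_composition: [0.25, 0.25, 0.25, 0.25]
frac_seed_match: 0.15
n_on_target: 1
reps_per_group: 3
mean_log_expression: 6.0
dispersion: 1000.0          # negative-binomial size; overdispersion = 1/size
offtarget_lfc_mean: -0.6
offtarget_lfc_sd: 0.2
offtarget_lfc_cap: 1.0      # |log2FC| ceiling: off-target changes stay within twofold
ontarget_lfc: -2.5
rng_seed: 20260930
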