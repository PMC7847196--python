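# Full PDX-like power grid for `xenopower power`.
# 1000 replicates per cell is the standard for two-decimal power tables;
# use `--reps` on the command line for a quick desk run.
params: pdx
tgi_targets: [50, 100]
n_per_arm: [5, 8, 10, 12, 15]
horizons: [14, 21, 28]
methods: [empirical, mixed]
reps: 1000
seed: 0
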