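# Representative CDX-like control parameters: same typical growth as the
# PDX set but with the much lower between-animal variability of an
# established cell line.  Synthetic reference values, NOT estimates fitted
# to any real study.
mu1: 1.29      # log mm: baseline radius ~3.6 mm (~200 mm3)
sigma1: 0.05
mu2: -2.40     # log mm/day
sigma2: 0.15   # low growth-rate heterogeneity
sigma3: 0.05   # tighter measurement error
c: 0.0
effect_scale: log_shift
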