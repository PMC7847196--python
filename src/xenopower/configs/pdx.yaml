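# Representative PDX-like control parameters for the linear-radius growth
# model.  These are synthetic reference values chosen for realism (baseline
# ~200 mm3 at randomisation, control reaching ~1000 mm3 by day 28, high
# between-animal growth-rate variability typical of patient-derived grafts);
# they are NOT estimates fitted to any real study.
mu1: 1.29      # log mm: baseline radius ~3.6 mm (~200 mm3)
sigma1: 0.10   # baseline CV ~10% (randomisation window)
mu2: -2.40     # log mm/day: radius growth ~0.091 mm/day
sigma2: 0.50   # growth-rate CV ~53%: PDX heterogeneity
sigma3: 0.10   # 10% proportional calliper error on the radius scale
c: 0.0
effect_scale: log_shift
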