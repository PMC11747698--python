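# Small end-to-end demonstration: 2 compound traits + 2 assessors,
# 300 progeny of 15 sires.  Runs in a couple of minutes on one CPU.
seed: 1
simulation:
  n_sires: 15
  n_progeny: 300
  dams_per_sire: 20        # unique dam per progeny
  n_grandsires: 5
  n_assessors: 2
  months_per_station: 2
  missing_assessors: [2]
  missing_observed_count: 250
reml:
  tol: 1.0e-6
  max_rounds: 300
  accelerate: true
performance:
  thr_ska: 0.2
  thr_anon: 1.5
  cutoff: 2
recursive:
  causal: [SKAt, ANONt]
combine:
  size: 2
  rank_by: h2
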