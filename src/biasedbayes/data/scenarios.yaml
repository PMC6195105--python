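# Named scenario fixtures. Values are plain probabilities (not logs).
disease_test:
  note: >
    Rare-disease screening problem: base rate 1/10,000; a test with 99%
    hit rate and 99% correct-rejection rate has come back positive.
    The Bayes posterior probability of illness is about 0.0098.
  support: [ill, healthy]
  prior: [0.0001, 0.9999]
  likelihood_positive: [0.99, 0.01]

gaussian_cue_combination:
  note: >
    Two Gaussian information sources combined, as in cue-combination /
    sensorimotor integration experiments where a learned prior over a
    visuomotor shift is merged with noisy midpoint feedback.
  prior: {mean: 0.0, variance: 1.0}
  likelihood: {mean: 3.0, variance: 1.0}

dot_motion_llr:
  note: >
    Momentary log-likelihood-ratio stream of a motion-discrimination
    stimulus: per-bin draws of N(llr_mean*dt, llr_sd^2*dt).
  llr_mean: 0.0
  llr_sd: 1.0
  dt: 0.01
  n_bins: 500

stroop_block:
  note: Balanced task x congruency Stroop trial list.
  n: 100
  palette: [red, green]
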