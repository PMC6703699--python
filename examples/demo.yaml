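# Small synthetic-cohort demonstration: three simulated participants, two
# ISS frequencies, retention+drift truth model, moderate observation noise.
truth_model: KAm
truth_params: {K: 0.02, A: 0.99, m: -0.004, D: 0.0, G: 0.0}
param_ranges:
  K: [0.015, 0.03]
frequencies: [3, 6]
n_participants: 3
sigma: 0.08
adaptation_type: two-way
seed: 1234
fit_models: [K, KAm, KAmG, KmDG, KAmDG]
n_starts: 8
fit_phenom: true
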