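# Default synthetic-cohort study conditions.
#
# n mirrors the size of a large nation-wide complete-case sample; the
# latent severity mixture has three equally likely classes whose means
# are 1.2 SD-units apart (within-class SD 0.35, ~unit total variance).
# All 17 items load 0.58 on the latent severity; per-item thresholds are
# solved at config build time to reproduce realistic marginal symptom
# means, so they are not listed here.  VAS couples to the latent
# severity (slope 20 per SD around an anchor of 50) with 25-point noise.
# A 1.43% per-cell missing rate leaves ~77% of patients complete.
generator:
  n: 28109
  class_weights: [0.3333333333333333, 0.3333333333333333, 0.3333333333333333]
  class_means: [-1.2, 0.0, 1.2]
  latent_sd: 0.35
  vas_anchor: 50.0
  vas_slope: 20.0
  vas_noise_sd: 25.0
  missing_rate: 0.0143
  seed: 0
seed: 0
bandwidths: [0.4, 0.6, 0.8, 1.0]
default_bandwidth: 0.8
repeatability_runs: 10
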