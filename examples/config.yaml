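# Example run configuration for the ribchron CLI.
# Any omitted block falls back to the shipped defaults (the study conditions).

population:
  n_specimens: 113
  age_mean: 46.64
  age_sd: 16.33
  age_min: 12
  age_max: 84
  sex_fraction_male: 0.6814   # 77 / 113

render:
  indents_per_site: 8         # per quadrant per compartment (4 x 8 x 2 curves)
  site_scatter_rel: 0.01
  xrd_noise_frac: 0.15
  mask_shape: [256, 256]

model:
  direction: both             # stepwise moves: both | forward | backward
  start: empty                # empty | full
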