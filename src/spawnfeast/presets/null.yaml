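# Null: activity is constant-rate Poisson and scat composition ignores egg
# mass, so no predictor carries signal; a well-behaved importance analysis
# should report pseudo-R^2 near zero.
bear_beta0: 0.0
bear_beta_egg: 0.0
bear_beta_amph: 0.0
bear_beta_doy: 0.0
egg_scat_gain: 0.0
scat_alphas:
  brown_algae: 2.0
  seagrasses: 2.0
  graminoids: 1.5
  amphipods: 1.0
  forbs: 0.3
  herring_eggs: 0.3
  trees_shrubs: 0.6
  gravel: 0.4
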