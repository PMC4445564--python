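# Strong egg effect: egg mass dominates both bear activity and the herring-egg
# share of scats; used for parameter-recovery experiments.
spawn_fraction: 0.7
bear_beta0: -1.2
bear_beta_egg: 1.8
bear_beta_amph: 0.6
bear_beta_doy: 0.8
egg_scat_gain: 6.0
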