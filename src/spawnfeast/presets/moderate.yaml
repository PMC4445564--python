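# Moderate resource effect: bear activity and scat egg share respond to egg
# mass but other drivers (emergence date, baseline) retain weight.
bear_beta0: -1.0
bear_beta_egg: 1.2
bear_beta_amph: 0.8
bear_beta_doy: 1.0
egg_scat_gain: 2.0
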