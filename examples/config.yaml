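# glucodyn pipeline configuration template.
#
# Every subcommand accepts --config with this file; --seed on the
# command line overrides the seed given here.

cohort:
  # animals per intervention x sex group (the emulated design uses 8)
  n_per_group: 8
  # glucose measurement noise, mg/dL (0 gives exactly the group-true curves)
  noise_sd_mgdl: 5.0
  # coefficient of variation of the lognormal per-animal multipliers
  # applied to the amplitude A and setpoint G0
  animal_effect_cv: 0.08
  # master seed; all randomness (animals, noise, spectra) derives from it
  seed: 0
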