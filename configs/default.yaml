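# Full default configuration for `wristcal run-all`.
# Omitted keys fall back to the same values; activity profiles default to the
# packaged reference profiles (published per-activity quantiles) and can be
# overridden here with a generator.activities list of
# {name, posture, dominant: [q25,q50,q75], non_dominant: [q25,q50,q75], rho, ...}.

generator:
  n_children: 167          # unique children in the calibration cohort
  epochs_per_activity: 60  # 5 min of 5-s epochs per activity
  p_stand: 0.05            # chance a seated session is contaminated by standing
  child_effect_sd: 0.3     # log-scale SD of the per-child multiplicative effect
  seed: 0
  handedness_right: 0.9

bootstrap:
  B: 100                   # clustered bootstrap replicates
  alpha: 0.05
  seed: 1

calibration:
  k: 10                    # folds within the calibration children
  calibration_fraction: 0.5988023952095808   # 100 / 167 children
  seed: 2
  signals: [axis1, axis2, axis3, vm]
  mode: cv                 # or "repeats" (Monte Carlo hold-outs)
  fold_eval: held_out      # or "train"
  pooled_sedentary: false
  validation_bootstrap_B: 200

output_dir: wristcal_output
log_level: INFO
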