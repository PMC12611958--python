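# Cohort simulation configuration
n_subjects: 10
artifact_time: 5.68
noise_sd_marker: 0.0   # mm
noise_sd_force: 0.0    # N
distributions:
  trigger_loaded: [476.75, 33.11]   # N
  stretch_loaded: [274.79, 52.08]   # N
  trigger_duration: [0.35, 0.03]    # s
  extension: [4.39, 1.02]           # mm
  rot_pre: [68.6, 2.37]             # deg
  rot_post: [73.7, 1.34]            # deg
  baseline1: [60.0, 8.0]            # N
  baseline2: [300.0, 30.0]          # N
  artifact_peak2: [514.1, 25.0]     # N
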