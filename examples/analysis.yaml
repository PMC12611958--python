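# Analysis configuration (all keys optional; defaults shown)
marker_cutoff_hz: 10.0
force_cutoff_hz: 50.0
filter_order: 4
min_event_n: 50.0
onset_floor_n: 10.0
onset_frac: 0.05
sustain_s: 0.05
b_rule: local_min          # or dfdt
artifact_drop_n: 30.0
artifact_rise_n: 100.0
angle_convention: twist_z  # or cardan_xyz
onset_rule: quadratic_fit  # or velocity_threshold
trigger_offset_s: 0.0
alias_map:
  R_ACROMION: shoulder_peak_right
  L_ACROMION: shoulder_peak_left
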