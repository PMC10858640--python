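# Example pipeline configuration.
# Trajectory, engine and telemetry sections are optional; omitted
# sections use the package defaults (full-cohort study conditions).
cohort:
  n_event_patients: 80
  n_control_patients: 240
  total_events: 114
  follow_up_days: [300, 1000]
  transmission_probability: 0.9
  seed: 11

engine:
  nominal_threshold: 45.0
  recovery_offset: 10.0
  stable_exceed_days: 2
  min_transmission_rate: 0.55
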