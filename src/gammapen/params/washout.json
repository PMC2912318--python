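{
 "amp_noise_cv": 0.25,
 "artifact_amp": 1500.0,
 "background_sd": 8.0,
 "burst_amp": 100.0,
 "burst_window_ms": [
  100.0,
  300.0
 ],
 "desync_frac": 0.3,
 "f0": 60.0,
 "fs_raw": 100000.0,
 "late_irregular_gain": 0.35,
 "latency_ms": 100.0,
 "phase_jitter_sd": 0.1,
 "pre_stim_ms": 50.0,
 "provenance": {
  "calibration_achieved_mean_apen": 0.4573370944832364,
  "calibration_knob": "desync_frac",
  "calibration_n_reps": 400,
  "calibration_seed": 777000,
  "calibration_target_apen": 0.46
 },
 "trace_end_ms": 500.0
}
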