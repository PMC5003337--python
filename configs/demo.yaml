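# Demo analysis: paper-scale design, reduced grid resolution for speed.
# An eyes-only induced gamma burst near 226 ms / 121 Hz is injected so the
# first-presentation main effect of stimulus type has something to find.
seed: 42
n_participants: 6
freq_step_hz: 8.0
time_decim: 8
single_precision: true
reml_pixels: 768
presentations: [first, second]
noise:
  one_over_f_exponent: 1.0
  background_sd_uv: 30.0
effects:
  amplitude_jitter_cv: 0.2
  bursts:
    - center_time_ms: 226.0
      center_freq_hz: 121.0
      time_fwhm_ms: 22.0
      freq_bandwidth_hz: 40.0
      amplitude_uv: 8.0
      condition: {stimulus_type: eyes}
      hemispheres: [left, right]
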