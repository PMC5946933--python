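{
  "label": "synthetic_profile_1",
  "n_impulses": 139,
  "source_duration": 62.0,
  "n_fft": 256,
  "sample_rate": 44100.0
}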