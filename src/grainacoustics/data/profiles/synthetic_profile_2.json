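{
  "label": "synthetic_profile_2",
  "n_impulses": 33,
  "source_duration": 20.0,
  "n_fft": 256,
  "sample_rate": 44100.0
}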