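{
  "input_channels": 3,
  "input_size": [16, 16],
  "stem_channels": 32,
  "blocks": [
    {"channels": 88, "n_convbn": 2, "se_ratio": 4, "use_residual": true, "stride": 2},
    {"channels": 64, "n_convbn": 2, "se_ratio": 4, "use_residual": true, "stride": 1},
    {"channels": 16, "n_convbn": 2, "se_ratio": 4, "use_residual": true, "stride": 2}
  ],
  "n_classes": 3,
  "ablation_mode": "full",
  "bn_eps": 1e-05
}
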