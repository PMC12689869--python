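{
  "in_channels": 1,
  "num_classes": 3,
  "stage_widths": [32, 64, 128, 252, 256],
  "miaf_heads": 4,
  "token_budget": 4096,
  "nominal_size": [512, 512],
  "seed": 0,
  "disable_convfft": false,
  "disable_fsmf": false,
  "disable_maha": false,
  "disable_gmca": false,
  "single_branch": false,
  "gmca_combine": "add"
}
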