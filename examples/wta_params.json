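{
  "max_mm5": 3,
  "max_mm3": 3,
  "search_range5": 46,
  "search_range3": 46,
  "occurrence": "keep",
  "continuous": true,
  "min_len": 50,
  "max_len": null,
  "max_n_percent": 5.0,
  "dereplicate": true,
  "split": true,
  "split_max_mm": 3
}
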