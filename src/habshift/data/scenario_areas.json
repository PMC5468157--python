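{
  "area_current_km2": 4810.0,
  "area_future_km2": 4529.0,
  "area_overlap_km2": 3823.0
}
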