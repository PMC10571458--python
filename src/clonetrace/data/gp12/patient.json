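{
 "patient_id": "GP12",
 "age_rp": 58.7,
 "index_samples": [
  "1-RMidApicalCA",
  "2-LMidApicalCA"
 ]
}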