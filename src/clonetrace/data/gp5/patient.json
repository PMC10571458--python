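{
 "patient_id": "GP5",
 "age_rp": 63.8,
 "index_samples": [
  "4-RCA2",
  "5-RCA3"
 ]
}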