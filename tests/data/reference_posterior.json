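{
 "mode": [
  0.6540907428608156,
  -4.589236907821653
 ],
 "free_energy": 300.40456216224084,
 "seed": 42,
 "config": "examples/toy_config.json"
}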