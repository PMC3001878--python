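{
 "observer": {"beta": 2.0, "k": 0.01, "sigma2": 0.0025},
 "n_trials": 100,
 "prior": {"mean": [0.0, 0.0], "sd": [10.0, 10.0], "names": ["log_beta", "log_k"]},
 "options": {"n_starts": 5},
 "replicates": 10,
 "candidates": [
  {"id": "informative_prior",
   "observer": {"beta": 2.0, "k": 0.01, "sigma2": 0.0025},
   "prior": {"mean": [0.0, 0.0], "sd": [10.0, 10.0]}},
  {"id": "near_flat_prior",
   "observer": {"beta": 2.0, "k": 0.01, "sigma2": 0.0025},
   "prior": {"mean": [-4.605170185988091, 0.0], "sd": [0.001, 10.0]}}
 ]
}
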