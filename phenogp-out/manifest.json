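{
  "seed": 0,
  "version": "0.1.0",
  "config": {
    "preset": "not-a-preset",
    "seed": 0,
    "n_markers": 1000,
    "trait": "gy",
    "window": "until_flowering",
    "models": [
      "M1",
      "M2",
      "M3",
      "M4",
      "M5",
      "M6"
    ],
    "cv_k": 5,
    "cv_repeats": 5,
    "gibbs_iter": 2000,
    "gibbs_burn_in": 500,
    "gibbs_thin": 2,
    "reml_tol": 1e-06,
    "reml_max_iter": 200,
    "out_dir": "phenogp-out"
  }
}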