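{
 "_comment": "Example piecewise-exponential growth demography (ancestral equilibrium followed by recent exponential growth), with weak negative selection across the site class. Epochs are listed most ancient first. Substitute published epoch parameters here to run a specific inferred human history; keep 2n below sqrt(8*N_min) for the per-generation update.",
 "sample_size_n": 125,
 "epochs": [
  {"duration": 8000, "N_start": 8000, "N_end": 8000, "mode": "constant", "s": -0.0005, "mu": 0.25},
  {"duration": 2000, "N_start": 8000, "N_end": 24000, "mode": "exponential", "s": -0.0005, "mu": 0.25}
 ]
}
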