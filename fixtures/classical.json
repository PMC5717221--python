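{
  "model": "classical",
  "b": 4,
  "v": 16.0,
  "D_rw": 1.0,
  "n_particles": 40,
  "n_steps": 20,
  "seed": 2099646311,
  "parent_seed": 20260101,
  "theory": {
    "vacf": "vacf_delta",
    "msd": "msd_classical"
  }
}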