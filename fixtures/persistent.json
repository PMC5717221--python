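{
  "model": "persistent",
  "b": 4,
  "v": 16.0,
  "D_rw": 1.0,
  "beta": 5.0,
  "n_particles": 40,
  "n_steps": 20,
  "seed": 1583042157,
  "parent_seed": 20260101,
  "theory": {
    "vacf": "vacf_persistent",
    "msd": "msd_persistent"
  }
}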