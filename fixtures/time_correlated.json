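{
  "model": "time_correlated",
  "b": 4,
  "v": 16.0,
  "D_rw": 1.0,
  "vacf": {
    "family": "power_law",
    "C0": 0.5,
    "Delta": 0.016,
    "phi": 1.0
  },
  "ballistic_until_valid": true,
  "n_particles": 40,
  "n_steps": 20,
  "seed": 1972034085,
  "parent_seed": 20260101,
  "theory": {
    "vacf": "vacf_power_law",
    "msd": "msd_tc_power_law"
  }
}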