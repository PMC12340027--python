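{
  "experiment_id": "exp3",
  "varied_parameter": "frequency",
  "n_stimuli": 20,
  "stimulus_duration": 0.08,
  "inter_stimulus_interval": 0.04,
  "precision_levels": {
    "low": 16,
    "med": 32,
    "high": 64
  },
  "mean_change_levels": {
    "low": 0.25,
    "med": 0.5,
    "high": 1.0
  },
  "prompt": "surprise",
  "direction_task": true,
  "n_exemplars_per_condition": 10,
  "base_frequency": 500.0,
  "reference_level": 1.0,
  "centre_value": 0.0,
  "rove_range": 0.5
}
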