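{
  "experiment_id": "exp4",
  "varied_parameter": "intensity",
  "n_stimuli": 10,
  "stimulus_duration": 0.3,
  "inter_stimulus_interval": 0.04,
  "precision_levels": {
    "low": 0.03125,
    "med": 0.125,
    "high": 0.5
  },
  "mean_change_levels": {
    "low": 2.5,
    "med": 5.0,
    "high": 10.0
  },
  "prompt": "surprise",
  "direction_task": true,
  "n_exemplars_per_condition": 10,
  "base_frequency": 500.0,
  "reference_level": 1.0,
  "centre_value": -20.0,
  "rove_range": 3.0
}
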