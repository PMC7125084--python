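{
  "version": 1,
  "profiles": {
    "wild_type": {
      "name": "wild_type",
      "srl": {
        "clay": [0.63, 0.04],
        "compost": [0.51, 0.03],
        "flume": [0.44, 0.05]
      },
      "detach_hazard_ratio": 1.0,
      "empirical_b": -0.095,
      "plateau": null,
      "breakpoint": null,
      "rld_range": [3.0, 56.0],
      "reinforcement_a": 1.23,
      "mech_m1": 5.45e-3,
      "mech_m_max": 139.0
    },
    "cpc_try": {
      "name": "cpc_try",
      "srl": {
        "clay": [0.43, 0.07],
        "compost": [0.39, 0.02],
        "flume": [0.52, 0.10]
      },
      "detach_hazard_ratio": 6.369,
      "empirical_b": -0.069,
      "plateau": 0.268,
      "breakpoint": 19.0,
      "rld_range": [8.0, 48.0],
      "reinforcement_a": 0.50,
      "mech_m1": 3.815e-3,
      "mech_m_max": 88.0
    },
    "wer_myb23": {
      "name": "wer_myb23",
      "srl": {
        "clay": [1.02, 0.31],
        "compost": [0.53, 0.02],
        "flume": [0.58, 0.15]
      },
      "detach_hazard_ratio": 0.553,
      "empirical_b": -0.066,
      "plateau": null,
      "breakpoint": null,
      "rld_range": [5.0, 34.0],
      "reinforcement_a": 0.86,
      "mech_m1": 3.085e-3,
      "mech_m_max": 134.0
    }
  }
}
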