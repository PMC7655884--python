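{
  "name": "GV-IAT (English stimulus set)",
  "categories": {
    "target_a": {
      "label": "Gender violence",
      "stimuli": ["Attack", "Force", "Humiliate", "Hit", "Torture", "Infringe"]
    },
    "target_b": {
      "label": "Non gender violence",
      "stimuli": ["Support", "Collaborate", "Cooperate", "Empathize", "Respect", "Tolerate"]
    },
    "attribute_good": {
      "label": "Good",
      "stimuli": ["Wonderful", "Excellent", "Phenomenal", "Best", "Positive", "Optimum"]
    },
    "attribute_bad": {
      "label": "Bad",
      "stimuli": ["Horrible", "Terrible", "Disastrous", "Worst", "Negative", "Appalling"]
    }
  },
  "response_keys": {"left": "S", "right": "L"},
  "versions": {
    "1": [
      {"block": 1, "trials": 24, "phase": "practice"},
      {"block": 2, "trials": 24, "phase": "practice"},
      {"block": 3, "trials": 24, "phase": "critical_compatible"},
      {"block": 4, "trials": 48, "phase": "critical_compatible"},
      {"block": 5, "trials": 48, "phase": "practice"},
      {"block": 6, "trials": 24, "phase": "critical_incompatible"},
      {"block": 7, "trials": 48, "phase": "critical_incompatible"}
    ],
    "2": [
      {"block": 1, "trials": 24, "phase": "practice"},
      {"block": 2, "trials": 24, "phase": "practice"},
      {"block": 3, "trials": 24, "phase": "critical_incompatible"},
      {"block": 4, "trials": 48, "phase": "critical_incompatible"},
      {"block": 5, "trials": 48, "phase": "practice"},
      {"block": 6, "trials": 24, "phase": "critical_compatible"},
      {"block": 7, "trials": 48, "phase": "critical_compatible"}
    ]
  }
}
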