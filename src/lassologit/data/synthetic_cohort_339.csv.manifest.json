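{
  "n": 339,
  "spec": {
    "effect_log_odds": {
      "diagnosis_duration": -1.55,
      "morphology=adenocarcinoma": -1.96,
      "sex=female": 0.97
    },
    "intercept": null,
    "marginal_frequencies": {
      "chemotherapy": {
        "no": 0.6,
        "yes": 0.4
      },
      "family_history": {
        "no": 0.85,
        "yes": 0.15
      },
      "grade": {
        "moderate": 0.7964601769911505,
        "poor": 0.1710914454277286,
        "well": 0.032448377581120944
      },
      "metastasis": {
        "no": 0.7,
        "yes": 0.3
      },
      "morphology": {
        "adenocarcinoma": 0.775811209439528,
        "carcinoma": 0.15634218289085547,
        "neoplasm": 0.06784660766961652
      },
      "opium": {
        "no": 0.8,
        "yes": 0.2
      },
      "radiotherapy": {
        "no": 0.75,
        "yes": 0.25
      },
      "residence": {
        "rural": 0.1976401179941003,
        "urban": 0.8023598820058997
      },
      "sex": {
        "female": 0.36283185840707965,
        "male": 0.6371681415929203
      },
      "smoking": {
        "no": 0.7315634218289085,
        "yes": 0.26843657817109146
      },
      "stage": {
        "1": 0.02654867256637168,
        "2": 0.6047197640117994,
        "3": 0.26843657817109146,
        "4": 0.10029498525073746
      },
      "surgery": {
        "no": 0.5,
        "yes": 0.5
      }
    },
    "n": 339,
    "seed": 20,
    "target_prevalence": 0.575
  },
  "spec_sha256": "9f3d64439ce7bb3eb2e1a32f0dd0e91e1dbe1a438ff59f40689e0621b31f3910"
}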