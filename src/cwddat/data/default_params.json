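{
  "guilds": {
    "fungi": {
      "k_base": 0.48394703887811763,
      "T_opt_C": 25.0,
      "T_sigma_C": 10.0,
      "T_threshold_C": null,
      "substrate_multiplier": {
        "1": 1.1,
        "2": 0.95
      },
      "colonization_lag_d": 1334.2344867683457,
      "colonization_steepness_d": 130.59431534609882,
      "resource_decline": 0.0,
      "fragmentation_share": 0.05
    },
    "termites": {
      "k_base": 0.26772161076160467,
      "T_opt_C": 28.0,
      "T_sigma_C": 7.0,
      "T_threshold_C": 10.0,
      "substrate_multiplier": {
        "1": 1.0,
        "2": 1.0
      },
      "colonization_lag_d": 0.0,
      "colonization_steepness_d": 90.0,
      "resource_decline": 0.1980924796267694,
      "fragmentation_share": 0.05
    },
    "bacteria": {
      "k_base": 0.016313870297826487,
      "T_opt_C": 30.0,
      "T_sigma_C": 12.0,
      "T_threshold_C": null,
      "substrate_multiplier": {
        "1": 1.0,
        "2": 1.0
      },
      "colonization_lag_d": 700.0,
      "colonization_steepness_d": 200.0,
      "resource_decline": 0.0,
      "fragmentation_share": 0.0
    },
    "beetles": {
      "k_base": 0.005,
      "T_opt_C": 24.0,
      "T_sigma_C": 8.0,
      "T_threshold_C": 8.0,
      "substrate_multiplier": {
        "1": 1.0,
        "2": 1.0
      },
      "colonization_lag_d": 0.0,
      "colonization_steepness_d": 90.0,
      "resource_decline": 0.3,
      "fragmentation_share": 0.3
    }
  },
  "size_exponent": 0.3,
  "reference_diameter_cm": 15.0,
  "standing_multiplier": 0.45,
  "doc_leach_coeff": 0.008957495274398508,
  "poc_coeff": 0.0004208444051376826,
  "forest_floor_k": 0.5,
  "doc_retention": 0.853,
  "carbon_fraction": 0.492
}
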