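{
  "name": "GEMM NCD+LRI hazard-ratio coefficients, China-cohort-inclusive variant",
  "provenance": "Global Exposure Mortality Model (Burnett et al. 2018, PNAS 115:9592-9597), nonaccidental (noncommunicable disease + lower respiratory infection) mortality. Shape log RR(z) = theta * log(1 + z/alpha) / (1 + exp(-(z - mu)/nu)), z = max(0, C - cmin). Standard errors shipped for reference; parametric uncertainty is not propagated.",
  "cmin": 2.4,
  "all_age": {"theta": 0.1430, "se": 0.01807, "alpha": 1.6, "mu": 15.5, "nu": 36.8},
  "age_groups": {
    "30-34": {"theta": 0.1585, "se": 0.01477, "alpha": 1.6, "mu": 15.5, "nu": 36.8},
    "35-39": {"theta": 0.1577, "se": 0.01470, "alpha": 1.6, "mu": 15.5, "nu": 36.8},
    "40-44": {"theta": 0.1570, "se": 0.01463, "alpha": 1.6, "mu": 15.5, "nu": 36.8},
    "45-49": {"theta": 0.1558, "se": 0.01450, "alpha": 1.6, "mu": 15.5, "nu": 36.8},
    "50-54": {"theta": 0.1532, "se": 0.01425, "alpha": 1.6, "mu": 15.5, "nu": 36.8},
    "55-59": {"theta": 0.1499, "se": 0.01394, "alpha": 1.6, "mu": 15.5, "nu": 36.8},
    "60-64": {"theta": 0.1462, "se": 0.01361, "alpha": 1.6, "mu": 15.5, "nu": 36.8},
    "65-69": {"theta": 0.1421, "se": 0.01325, "alpha": 1.6, "mu": 15.5, "nu": 36.8},
    "70-74": {"theta": 0.1374, "se": 0.01284, "alpha": 1.6, "mu": 15.5, "nu": 36.8},
    "75-79": {"theta": 0.1319, "se": 0.01234, "alpha": 1.6, "mu": 15.5, "nu": 36.8},
    "80-84": {"theta": 0.1253, "se": 0.01174, "alpha": 1.6, "mu": 15.5, "nu": 36.8},
    "85+":   {"theta": 0.1141, "se": 0.01071, "alpha": 1.6, "mu": 15.5, "nu": 36.8}
  }
}
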