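{
  "H0_minus": 14.309761117962463,
  "H0_plus": 15.57464772539698,
  "_meta": {
    "provenance": "derived by sleepdyn.mapping.calibrate_switch_from_pr from the canonical human mutual-inhibition parameter set (params.pr_human); regenerated and checked by the test-suite",
    "units": {
      "H0_minus": "pressure",
      "H0_plus": "pressure",
      "chi_s": "h",
      "chi_w": "h",
      "circadian.amplitude": "pressure",
      "lower": "pressure",
      "mu": "pressure"
    }
  },
  "chi_s": 45.0,
  "chi_w": 45.0,
  "circadian": {
    "alpha": 0.3490658503988659,
    "amplitude": -2.9,
    "coefficients": [
      1.0
    ],
    "omega": 0.2617993877991494
  },
  "kind": "two_process",
  "lower": 0.0,
  "mu": 21.552487855268907
}
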