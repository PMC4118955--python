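{
  "A": 1.3,
  "D0_v": -13.05,
  "Q_half_sat": 1.0,
  "Q_max": 100.0,
  "_meta": {
    "provenance": "canonical human parameter set of the mutual-inhibition (Phillips-Robinson) sleep-wake model, mean circadian drive absorbed into D0_v, all weights positive",
    "units": {
      "A": "mV",
      "D0_v": "mV",
      "Q_max": "1/s",
      "chi": "h",
      "circadian.amplitude": "mV",
      "mu_h": "pressure s",
      "nu_mv": "mV s",
      "nu_vh": "mV/pressure",
      "nu_vm": "mV s",
      "sigma": "mV",
      "tau": "s",
      "theta": "mV"
    }
  },
  "asymptote_form": "linear",
  "chi": 45.0,
  "circadian": {
    "alpha": 0.3490658503988659,
    "amplitude": 2.9,
    "coefficients": [
      1.0
    ],
    "omega": 0.2617993877991494
  },
  "kind": "pr",
  "mu_h": 4.4,
  "nu_mv": 1.8,
  "nu_vh": 1.0,
  "nu_vm": 2.1,
  "sigma": 3.0,
  "tau": 10.0,
  "theta": 10.0
}
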