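{
  "name": "CA",
  "wavelength_window": [330.0, 860.0],
  "concentration_range": [500000.0, 4000000.0],
  "validity_floor": 10000.0,
  "components": [
    {
      "amplitude": {"family": "log_linear", "params": [-218.6, 41.1]},
      "center": {"family": "log_linear", "params": [-7884.0, 1130.0]},
      "width": {"family": "constant", "params": [2036.0]}
    },
    {
      "amplitude": {"family": "log_linear", "params": [-182.0, 33.36]},
      "center": {"family": "constant", "params": [562.3]},
      "width": {"family": "constant", "params": [479.5]}
    }
  ]
}
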