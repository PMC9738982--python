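{
  "name": "CEM",
  "wavelength_window": [330.0, 860.0],
  "concentration_range": [100000.0, 1000000.0],
  "components": [
    {
      "amplitude": {"family": "beer_lambert_amplitude", "params": [7.67e-07]},
      "center": {"family": "constant", "params": [533.7]},
      "width": {"family": "power", "params": [6.32, 0.34]}
    },
    {
      "amplitude": {"family": "constant", "params": [12.21]},
      "center": {"family": "constant", "params": [936.1]},
      "width": {"family": "constant", "params": [177.2]}
    }
  ]
}
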