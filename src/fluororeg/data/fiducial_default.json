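{
  "bead_centers": [[0.0, 0.0, 25.0], [25.0, 0.0, 40.0], [0.0, 24.0, 60.0]],
  "pin_tip": [0.0, 0.0, -60.0],
  "labels": ["bead1", "bead2", "bead3"],
  "pin_radius": 2.0,
  "pin_top": [0.0, 0.0, 5.0]
}
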