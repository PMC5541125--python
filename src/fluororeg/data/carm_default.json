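{
  "sid": 980.0,
  "pixel_size": 0.224,
  "detector_diameter": 230.0,
  "principal_point": [515.0, 515.0],
  "image_shape": [1030, 1030],
  "distortion": null
}
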