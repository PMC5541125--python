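{
  "name": "phantom-like",
  "pixel_noise": 0.01,
  "feature_jitter_px": 0.25,
  "contour_sigma_px": 0.5,
  "occlusion_fraction_lat": 0.0,
  "blur_sigma_px": 1.0,
  "distortion": false
}
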