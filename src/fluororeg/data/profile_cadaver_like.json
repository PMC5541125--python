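{
  "name": "cadaver-like",
  "pixel_noise": 0.02,
  "feature_jitter_px": 0.5,
  "contour_sigma_px": 1.5,
  "occlusion_fraction_lat": 0.25,
  "blur_sigma_px": 1.0,
  "distortion": false
}
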