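{
  "comment": "Synthetic head-and-neck-like cross-section: smaller ellipse, an anterior air cavity, a posterior bone-like disc, lateralized CTV. Lengths in mm.",
  "grid_shape": [115, 95],
  "pixel_spacing": [2.0, 2.0],
  "body": {"center": [0.0, 0.0], "semiaxes": [85.0, 105.0]},
  "background_sp": 1.0,
  "inserts": [
    {"shape": "disc", "center": [0.0, 25.0], "size": 15.0, "sp": 0.0},
    {"shape": "disc", "center": [0.0, -60.0], "size": 12.0, "sp": 1.431}
  ],
  "ctv": {"center": [25.0, -10.0], "radius": 20.0}
}
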