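{
  "comment": "Synthetic pelvis-like cross-section: wide elliptical body, two lateral high-density femoral-head discs, central prostate-like CTV. Lengths in mm, +y anterior, +x patient left.",
  "grid_shape": [140, 190],
  "pixel_spacing": [2.0, 2.0],
  "body": {"center": [0.0, 0.0], "semiaxes": [175.0, 130.0]},
  "background_sp": 1.0,
  "inserts": [
    {"shape": "disc", "center": [95.0, -20.0], "size": 22.0, "sp": 1.622},
    {"shape": "disc", "center": [-95.0, -20.0], "size": 22.0, "sp": 1.622}
  ],
  "ctv": {"center": [0.0, -20.0], "radius": 25.0}
}
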