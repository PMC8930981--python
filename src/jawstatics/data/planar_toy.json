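{
  "units": {"length": "mm", "area": "cm2"},
  "joints": {"left": [0.0, 4.0, 0.0], "right": [0.0, -4.0, 0.0]},
  "gape_reference_deg": 0.0,
  "muscles": [
    {
      "name": "external_adductor_left",
      "group": "external_adductor",
      "side": "left",
      "origin": [10.0, 3.0, 18.0],
      "insertion": [10.0, 3.0, 0.0],
      "acsa": 0.5
    },
    {
      "name": "external_adductor_right",
      "group": "external_adductor",
      "side": "right",
      "origin": [10.0, -3.0, 18.0],
      "insertion": [10.0, -3.0, 0.0],
      "acsa": 0.5
    }
  ],
  "bite_points": [
    {"label": "jaw_tip", "position": [40.0, 0.0, 0.0]},
    {"label": "anterior_caniniform", "position": [32.0, 0.0, 0.0]},
    {"label": "posterior_caniniform", "position": [24.0, 0.0, 0.0]},
    {"label": "posterior_most", "position": [18.0, 0.0, 0.0]}
  ],
  "note": "Sagittal-plane toy: two mirrored vertical bundles totalling 30 N at a 10 mm in-lever; closed-pose bite force at a bite point r mm anterior is 300/r N."
}
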