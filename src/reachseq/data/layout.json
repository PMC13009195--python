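{
  "version": 1,
  "units": "mm",
  "start": [0.0, 0.0],
  "start_radius": 35.0,
  "targets": {
    "blue": {"center": [-65.0, 157.0], "radius": 55.0},
    "red": {"center": [65.0, 157.0], "radius": 55.0},
    "olive": {"center": [-215.0, 120.0], "radius": 35.0},
    "pink": {"center": [215.0, 120.0], "radius": 35.0},
    "lilac": {"center": [0.0, 330.0], "radius": 45.0}
  },
  "sequences": [
    ["blue", "olive"],
    ["blue", "pink"],
    ["blue", "lilac"],
    ["red", "olive"],
    ["red", "pink"],
    ["red", "lilac"]
  ]
}
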