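{
  "_comment": "Atomic units. Exponents over base dimensions (mass, length, time); scale converts one unit to the canonical basis (mg, m, day). Compound units such as 'mg/m^3' or 'm^3/(day*kg)' are parsed from these atoms.",
  "units": {
    "1":   {"dim": [0, 0, 0], "scale": 1.0},
    "ug":  {"dim": [1, 0, 0], "scale": 1e-3},
    "mg":  {"dim": [1, 0, 0], "scale": 1.0},
    "g":   {"dim": [1, 0, 0], "scale": 1e3},
    "kg":  {"dim": [1, 0, 0], "scale": 1e6},
    "um":  {"dim": [0, 1, 0], "scale": 1e-6},
    "mm":  {"dim": [0, 1, 0], "scale": 1e-3},
    "cm":  {"dim": [0, 1, 0], "scale": 1e-2},
    "m":   {"dim": [0, 1, 0], "scale": 1.0},
    "ul":  {"dim": [0, 3, 0], "scale": 1e-9},
    "ml":  {"dim": [0, 3, 0], "scale": 1e-6},
    "l":   {"dim": [0, 3, 0], "scale": 1e-3},
    "s":   {"dim": [0, 0, 1], "scale": 1.1574074074074073e-5},
    "min": {"dim": [0, 0, 1], "scale": 6.944444444444444e-4},
    "h":   {"dim": [0, 0, 1], "scale": 0.041666666666666664},
    "day": {"dim": [0, 0, 1], "scale": 1.0},
    "d":   {"dim": [0, 0, 1], "scale": 1.0}
  }
}
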