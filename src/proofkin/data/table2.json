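{
  "k1":     {"value": 1100.0,  "units": "uM-1 s-1", "status": "free",        "bounds": [1e-2, 1e5]},
  "km1":    {"value": 44.1,    "units": "s-1",      "status": "free",        "bounds": [1e-3, 1e6]},
  "k2":     {"value": 5000.0,  "units": "s-1",      "status": "lower-limit", "bounds": [5000.0, 1e7]},
  "km2":    {"value": 1670.0,  "units": "s-1",      "status": "free",        "bounds": [1e-3, 1e6]},
  "k3":     {"value": 443.0,   "units": "s-1",      "status": "free",        "bounds": [1e-3, 1e6]},
  "km3":    {"value": 0.0518,  "units": "uM-1 s-1", "status": "free",        "bounds": [1e-6, 1e4]},
  "k3_2":   {"value": 546.0,   "units": "s-1",      "status": "free",        "bounds": [1e-3, 1e6]},
  "k3_3":   {"value": 631.0,   "units": "s-1",      "status": "free",        "bounds": [1e-3, 1e6]},
  "k3_late":{"value": 500.0,   "units": "s-1",      "status": "locked",      "bounds": [1e-3, 1e6]},
  "kI_on":  {"value": 100.0,   "units": "uM-1 s-1", "status": "locked",      "bounds": [1e-2, 1e4]},
  "KI":     {"value": 5.65,    "units": "mM",       "status": "free",        "bounds": [1e-3, 1e3]}
}
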