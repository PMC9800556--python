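{
  "k1":    {"value": 114.0,  "units": "uM-1 s-1", "status": "free",        "bounds": [1e-2, 1e5]},
  "km1":   {"value": 0.372,  "units": "s-1",      "status": "free",        "bounds": [1e-4, 1e5]},
  "k2":    {"value": 451.0,  "units": "uM-1 s-1", "status": "free",        "bounds": [1e-2, 1e5]},
  "km2":   {"value": 2.44,   "units": "s-1",      "status": "free",        "bounds": [1e-4, 1e5]},
  "k3":    {"value": 382.0,  "units": "uM-1 s-1", "status": "free",        "bounds": [1e-2, 1e5]},
  "km3":   {"value": 0.231,  "units": "s-1",      "status": "free",        "bounds": [1e-4, 1e5]},
  "k5":    {"value": 4.87,   "units": "s-1",      "status": "free",        "bounds": [1e-4, 1e5]},
  "km5":   {"value": 2.94,   "units": "s-1",      "status": "free",        "bounds": [1e-4, 1e5]},
  "k6":    {"value": 5000.0, "units": "s-1",      "status": "lower-limit", "bounds": [5000.0, 1e7]},
  "k7":    {"value": 59.6,   "units": "s-1",      "status": "free",        "bounds": [1e-3, 1e6]},
  "k4act": {"value": 2.81,   "units": "s-1",      "status": "free",        "bounds": [1e-4, 1e5]},
  "k5act": {"value": 7.83,   "units": "s-1",      "status": "free",        "bounds": [1e-4, 1e5]},
  "kext":  {"value": 300.0,  "units": "s-1",      "status": "lower-limit", "bounds": [300.0, 1e6]}
}
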