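{
  "k1":      {"value": 278.0,   "units": "uM-1 s-1", "status": "free",        "bounds": [1e-2, 1e5]},
  "km1":     {"value": 0.193,   "units": "s-1",      "status": "free",        "bounds": [1e-4, 1e5]},
  "k2":      {"value": 701.0,   "units": "uM-1 s-1", "status": "free",        "bounds": [1e-2, 1e5]},
  "km2":     {"value": 6.23,    "units": "s-1",      "status": "free",        "bounds": [1e-4, 1e5]},
  "k3":      {"value": 6.66,    "units": "uM-1 s-1", "status": "upper-limit", "bounds": [1e-3, 6.66]},
  "km3":     {"value": 0.2,     "units": "s-1",      "status": "locked",      "bounds": [1e-4, 1e5]},
  "k4":      {"value": 1.48,    "units": "s-1",      "status": "free",        "bounds": [1e-4, 1e5]},
  "km4":     {"value": 0.722,   "units": "s-1",      "status": "free",        "bounds": [1e-4, 1e5]},
  "k5":      {"value": 4.56,    "units": "s-1",      "status": "free",        "bounds": [1e-4, 1e5]},
  "km5":     {"value": 0.357,   "units": "s-1",      "status": "free",        "bounds": [1e-4, 1e5]},
  "k6":      {"value": 5000.0,  "units": "s-1",      "status": "lower-limit", "bounds": [5000.0, 1e7]},
  "k7":      {"value": 43.1,    "units": "s-1",      "status": "free",        "bounds": [1e-3, 1e6]},
  "k8":      {"value": 4.93,    "units": "s-1",      "status": "free",        "bounds": [1e-4, 1e5]},
  "km8":     {"value": 16200.0, "units": "s-1",      "status": "free",        "bounds": [1e-2, 1e7]},
  "k9":      {"value": 0.372,   "units": "s-1",      "status": "locked",      "bounds": [1e-4, 1e5]},
  "k10":     {"value": 2.44,    "units": "s-1",      "status": "locked",      "bounds": [1e-4, 1e5]},
  "k11":     {"value": 101.0,   "units": "s-1",      "status": "lower-limit", "bounds": [101.0, 1e6]},
  "k12":     {"value": 60.0,    "units": "s-1",      "status": "locked",      "bounds": [1e-3, 1e6]},
  "k13":     {"value": 4.74,    "units": "s-1",      "status": "free",        "bounds": [1e-4, 1e5]},
  "k14":     {"value": 0.2,     "units": "s-1",      "status": "locked",      "bounds": [1e-4, 1e5]},
  "k4act":   {"value": 1.5,     "units": "s-1",      "status": "free",        "bounds": [1e-4, 1e5]},
  "k5act":   {"value": 7.08,    "units": "s-1",      "status": "free",        "bounds": [1e-4, 1e5]},
  "k8act":   {"value": 43.5,    "units": "s-1",      "status": "free",        "bounds": [1e-4, 1e5]},
  "kext":    {"value": 300.0,   "units": "s-1",      "status": "lower-limit", "bounds": [300.0, 1e6]},
  "kon_x26": {"value": 114.0,   "units": "uM-1 s-1", "status": "locked",      "bounds": [1e-2, 1e5]},
  "kon_i26": {"value": 451.0,   "units": "uM-1 s-1", "status": "locked",      "bounds": [1e-2, 1e5]},
  "kon_p26": {"value": 382.0,   "units": "uM-1 s-1", "status": "locked",      "bounds": [1e-2, 1e5]}
}
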