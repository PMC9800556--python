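{
 "name": "ssdna_titration",
 "substrate": "ssdna",
 "kind": "titration",
 "signal": "fluorescence",
 "dna_uM": 0.025,
 "enzyme_uM": 0.0,
 "trap_uM": 0.0,
 "dcmp_uM": 0.0,
 "dntps": false,
 "chemistry": false,
 "time_max_s": 1.0,
 "time_min_s": 0.001,
 "n_times": 50,
 "time_spacing": "linear",
 "series": [],
 "titration": {
  "n_points": 24,
  "titrant_max_uM": 0.4,
  "cuvette_ul": 280.0,
  "added_ul": 20.5,
  "epsilon": 0.805
 }
}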