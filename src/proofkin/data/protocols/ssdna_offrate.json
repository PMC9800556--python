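{
 "name": "ssdna_offrate",
 "substrate": "ssdna",
 "kind": "trap-offrate",
 "signal": "anisotropy",
 "dna_uM": 0.05,
 "enzyme_uM": 0.075,
 "trap_uM": 1.0,
 "dcmp_uM": 0.0,
 "dntps": false,
 "chemistry": false,
 "time_max_s": 0.12,
 "time_min_s": 0.001,
 "n_times": 50,
 "time_spacing": "linear",
 "series": [],
 "titration": null
}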