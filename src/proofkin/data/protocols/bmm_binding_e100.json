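{
 "name": "bmm_binding_e100",
 "substrate": "bmm",
 "kind": "mix-binding",
 "signal": "anisotropy",
 "dna_uM": 0.025,
 "enzyme_uM": 0.1,
 "trap_uM": 0.0,
 "dcmp_uM": 0.0,
 "dntps": false,
 "chemistry": false,
 "time_max_s": 0.05,
 "time_min_s": 0.001,
 "n_times": 40,
 "time_spacing": "linear",
 "series": [],
 "titration": null
}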