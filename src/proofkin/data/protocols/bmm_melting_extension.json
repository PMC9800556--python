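{
 "name": "bmm_melting_extension",
 "substrate": "bmm",
 "kind": "excision-extension",
 "signal": "fluorescence",
 "dna_uM": 0.025,
 "enzyme_uM": 0.04,
 "trap_uM": 0.6,
 "dcmp_uM": 0.0,
 "dntps": true,
 "chemistry": true,
 "time_max_s": 5.0,
 "time_min_s": 0.0015,
 "n_times": 60,
 "time_spacing": "log",
 "series": [],
 "titration": null
}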