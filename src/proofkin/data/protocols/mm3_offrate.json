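{
 "name": "mm3_offrate",
 "substrate": "mm3",
 "kind": "trap-offrate",
 "signal": "fluorescence",
 "dna_uM": 0.025,
 "enzyme_uM": 0.03,
 "trap_uM": 0.5,
 "dcmp_uM": 0.0,
 "dntps": false,
 "chemistry": false,
 "time_max_s": 12.0,
 "time_min_s": 0.001,
 "n_times": 60,
 "time_spacing": "linear",
 "series": [],
 "titration": null
}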