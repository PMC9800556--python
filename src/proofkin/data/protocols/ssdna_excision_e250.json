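{
 "name": "ssdna_excision_e250",
 "substrate": "ssdna",
 "kind": "quench-mix",
 "signal": "primer-length-table",
 "dna_uM": 0.15,
 "enzyme_uM": 0.25,
 "trap_uM": 0.0,
 "dcmp_uM": 0.0,
 "dntps": false,
 "chemistry": true,
 "time_max_s": 0.4,
 "time_min_s": 0.001,
 "n_times": 13,
 "time_spacing": "log",
 "series": [
  [
   "27",
   [
    27
   ]
  ],
  [
   "26",
   [
    26
   ]
  ],
  [
   "25",
   [
    25
   ]
  ],
  [
   "24",
   [
    24
   ]
  ]
 ],
 "titration": null
}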