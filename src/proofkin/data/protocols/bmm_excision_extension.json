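{
 "name": "bmm_excision_extension",
 "substrate": "bmm",
 "kind": "excision-extension",
 "signal": "primer-length-table",
 "dna_uM": 0.075,
 "enzyme_uM": 0.4,
 "trap_uM": 1.0,
 "dcmp_uM": 0.0,
 "dntps": true,
 "chemistry": true,
 "time_max_s": 2.0,
 "time_min_s": 0.002,
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
   "30",
   [
    30
   ]
  ]
 ],
 "titration": null
}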