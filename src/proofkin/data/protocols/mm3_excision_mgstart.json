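{
 "name": "mm3_excision_mgstart",
 "substrate": "mm3",
 "kind": "quench-preincubate-Mg",
 "signal": "primer-length-table",
 "dna_uM": 0.075,
 "enzyme_uM": 1.0,
 "trap_uM": 0.0,
 "dcmp_uM": 0.0,
 "dntps": false,
 "chemistry": true,
 "time_max_s": 3.0,
 "time_min_s": 0.002,
 "n_times": 14,
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
  ]
 ],
 "titration": null
}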