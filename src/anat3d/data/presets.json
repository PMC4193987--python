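[
  {"name": "bone", "lower": 382, "upper": 3071,
   "lower_inclusive": true, "upper_inclusive": true},
  {"name": "membrane", "upper": -50, "upper_inclusive": false},
  {"name": "air", "upper": -500, "upper_inclusive": true},
  {"name": "soft_canal", "lower": -45, "upper": -15,
   "lower_inclusive": true, "upper_inclusive": true},
  {"name": "ossicle", "lower": 1800, "upper": 3071,
   "lower_inclusive": true, "upper_inclusive": true}
]
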