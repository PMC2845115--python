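{
  "residue_mass": {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.2},
  "terminator_mass": {"A": 271.17, "C": 247.15, "G": 287.17, "T": 327.19},
  "terminal_adjustment": 18.02,
  "adduct_shifts": [["Na", 21.98], ["K", 37.95]],
  "min_terminator_gap": 8.0
}
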