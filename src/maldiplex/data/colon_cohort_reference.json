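{
  "description": "Observed mutation statistics from a 239-tumor stage II/III colon cancer cohort profiled by multiplexed SBE MALDI-TOF, with 39 paired metastatic lymph nodes.",
  "n_samples": 239,
  "mutation_counts": [
    ["ABL1", "F359V", 1],
    ["AKT1", "E17K", 1],
    ["BRAF", "D594V", 1],
    ["BRAF", "V600E", 28],
    ["KRAS", "G12A", 2],
    ["KRAS", "G12C", 10],
    ["KRAS", "G12D", 40],
    ["KRAS", "G12R", 3],
    ["KRAS", "G12S", 3],
    ["KRAS", "G12V", 20],
    ["KRAS", "G13D", 23],
    ["KRAS", "A59T", 1],
    ["KRAS", "Q61L", 1],
    ["KRAS", "Q61R", 1],
    ["MET", "R970C", 2],
    ["MET", "T992I", 6],
    ["NRAS", "G12C", 1],
    ["NRAS", "G12D", 4],
    ["NRAS", "G13R", 1],
    ["NRAS", "G13V", 1],
    ["NRAS", "Q61H", 1],
    ["NRAS", "Q61K", 1],
    ["PIK3CA", "R88Q", 5],
    ["PIK3CA", "C420R", 2],
    ["PIK3CA", "E542K", 9],
    ["PIK3CA", "E545K", 12],
    ["PIK3CA", "Q546K", 4],
    ["PIK3CA", "H701P", 1],
    ["PIK3CA", "H1047L", 1],
    ["PIK3CA", "H1047R", 14]
  ],
  "gene_single_freq_pct": {
    "KRAS": 43.7,
    "PIK3CA": 20.1,
    "BRAF": 11.8,
    "MET": 3.3,
    "NRAS": 3.8
  },
  "node_pairs": {
    "n_pairs": 39,
    "n_identical": 35,
    "n_node_mutations": 26,
    "primary_only_mutations": [
      ["BRAF", "V600E"],
      ["BRAF", "V600E"],
      ["PIK3CA", "H1047R"],
      ["KRAS", "G12D"]
    ]
  },
  "kras_pik3ca_ratio_bands": [
    {"n": 22, "low": 1.25, "high": 3.22},
    {"n": 7, "low": 0.93, "high": 1.13},
    {"n": 2, "low": 0.42, "high": 0.81}
  ],
  "paired_double_mutants": [
    {"sample": "C07-0388", "m1": ["KRAS", "G12D"], "m2": ["PIK3CA", "H1047R"],
     "primary": [0.45, 0.24], "node": [0.44, 0.27]},
    {"sample": "C07-0717", "m1": ["KRAS", "G13D"], "m2": ["PIK3CA", "H1047R"],
     "primary": [0.08, 0.07], "node": [0.09, 0.1]},
    {"sample": "C07-0940", "m1": ["KRAS", "G12D"], "m2": ["PIK3CA", "E542K"],
     "primary": [0.42, 0.22], "node": [0.34, 0.31]},
    {"sample": "C07-2244", "m1": ["KRAS", "G12C"], "m2": ["PIK3CA", "H1047R"],
     "primary": [0.37, 0.21], "node": [0.15, 0.0]},
    {"sample": "C07-1837", "m1": ["BRAF", "V600E"], "m2": ["PIK3CA", "H1047R"],
     "primary": [0.2, 0.12], "node": [0.22, 0.05]}
  ]
}
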