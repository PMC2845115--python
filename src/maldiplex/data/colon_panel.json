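{
 "mass_table": {
  "adduct_shifts": [
   [
    "Na",
    21.98
   ],
   [
    "K",
    37.95
   ]
  ],
  "min_terminator_gap": 8.0,
  "residue_mass": {
   "A": 313.21,
   "C": 289.18,
   "G": 329.21,
   "T": 304.2
  },
  "terminal_adjustment": 18.02,
  "terminator_mass": {
   "A": 271.17,
   "C": 247.15,
   "G": 287.17,
   "T": 327.19
  }
 },
 "max_plex": 9,
 "name": "colon-hotspot-v1",
 "pools": {
  "W1": [
   {
    "aa_label": "V600",
    "assay_id": "BRAF_15",
    "codon_pos": 2,
    "codon_ref": "GTG",
    "complex_group": "BRAF_V600",
    "gene": "BRAF",
    "kind": "complex",
    "mut_alleles": {
     "A": "V600E"
    },
    "primer_seq": "GTACGGGGCATGGGG",
    "wt_base": "T"
   },
   {
    "aa_label": "G13",
    "assay_id": "KRAS_4",
    "codon_pos": 2,
    "codon_ref": "GGC",
    "gene": "KRAS",
    "kind": "simple",
    "mut_alleles": {
     "A": "G13D"
    },
    "primer_seq": "GGTGACACGGGTATAGGT",
    "wt_base": "G"
   },
   {
    "aa_label": "G12",
    "assay_id": "NRAS_1",
    "codon_pos": 2,
    "codon_ref": "GGT",
    "complex_group": "NRAS_G12",
    "gene": "NRAS",
    "kind": "complex",
    "mut_alleles": {
     "A": "G12D",
     "C": "G12A",
     "T": "G12V"
    },
    "primer_seq": "GCCATCCGAGGTGGCAGTGAG",
    "wt_base": "G"
   },
   {
    "aa_label": "R88",
    "assay_id": "PIK3CA_1",
    "codon_pos": 2,
    "codon_ref": "CGA",
    "gene": "PIK3CA",
    "kind": "simple",
    "mut_alleles": {
     "A": "R88Q"
    },
    "primer_seq": "AGTCGGTAAAGCAACATGCACAGG",
    "wt_base": "G"
   },
   {
    "aa_label": "H1047",
    "assay_id": "PIK3CA_9",
    "codon_pos": 2,
    "codon_ref": "CAT",
    "gene": "PIK3CA",
    "kind": "simple",
    "mut_alleles": {
     "G": "H1047R",
     "T": "H1047L"
    },
    "primer_seq": "GTCAGGAAATCCTGATCCGCAGCGGGT",
    "wt_base": "A"
   }
  ],
  "W2": [
   {
    "aa_label": "V600",
    "assay_id": "BRAF_16",
    "codon_pos": 1,
    "codon_ref": "GTG",
    "complex_group": "BRAF_V600",
    "gene": "BRAF",
    "kind": "complex",
    "mut_alleles": {
     "A": "V600K",
     "C": "V600L",
     "T": "V600L"
    },
    "primer_seq": "CGACTTCATGGTAGCT",
    "wt_base": "G"
   },
   {
    "aa_label": "A59",
    "assay_id": "KRAS_5",
    "codon_pos": 1,
    "codon_ref": "GCA",
    "gene": "KRAS",
    "kind": "simple",
    "mut_alleles": {
     "A": "A59T"
    },
    "primer_seq": "AAGCTAATCGTTCATAACT",
    "wt_base": "G"
   },
   {
    "aa_label": "G12",
    "assay_id": "NRAS_2",
    "codon_pos": 1,
    "codon_ref": "GGT",
    "complex_group": "NRAS_G12",
    "gene": "NRAS",
    "kind": "complex",
    "mut_alleles": {
     "A": "G12S",
     "C": "G12R",
     "T": "G12C"
    },
    "primer_seq": "CCCAGCCATATGCTCGAACGCG",
    "wt_base": "G"
   },
   {
    "aa_label": "C420",
    "assay_id": "PIK3CA_3",
    "codon_pos": 1,
    "codon_ref": "TGT",
    "gene": "PIK3CA",
    "kind": "simple",
    "mut_alleles": {
     "C": "C420R"
    },
    "primer_seq": "ACGACTACCGTACGGACAACCCCGC",
    "wt_base": "T"
   }
  ],
  "W3": [
   {
    "aa_label": "D594",
    "assay_id": "BRAF_9",
    "codon_pos": 2,
    "codon_ref": "GAT",
    "gene": "BRAF",
    "kind": "simple",
    "mut_alleles": {
     "G": "D594G",
     "T": "D594V"
    },
    "primer_seq": "TGGGTAGGCGGGCCGG",
    "wt_base": "A"
   },
   {
    "aa_label": "Q61",
    "assay_id": "KRAS_7",
    "codon_pos": 2,
    "codon_ref": "CAA",
    "gene": "KRAS",
    "kind": "simple",
    "mut_alleles": {
     "G": "Q61R",
     "T": "Q61L"
    },
    "primer_seq": "GAGGTACAGTAGGGTACAA",
    "wt_base": "A"
   },
   {
    "aa_label": "G13",
    "assay_id": "NRAS_3",
    "codon_pos": 2,
    "codon_ref": "GGT",
    "complex_group": "NRAS_G13",
    "gene": "NRAS",
    "kind": "complex",
    "mut_alleles": {
     "A": "G13D",
     "C": "G13A",
     "T": "G13V"
    },
    "primer_seq": "TGCCGATGTTGAAGGGATGACT",
    "wt_base": "G"
   },
   {
    "aa_label": "E542",
    "assay_id": "PIK3CA_5",
    "codon_pos": 1,
    "codon_ref": "GAA",
    "gene": "PIK3CA",
    "kind": "simple",
    "mut_alleles": {
     "A": "E542K"
    },
    "primer_seq": "TGATCGCCAAAGAAAGTGACTCTGG",
    "wt_base": "G"
   }
  ],
  "W4": [
   {
    "aa_label": "Q61",
    "assay_id": "HRAS_6",
    "codon_pos": 2,
    "codon_ref": "CAG",
    "gene": "HRAS",
    "kind": "simple",
    "mut_alleles": {
     "T": "Q61L"
    },
    "primer_seq": "CCTAGAGCGGGTATCCC",
    "wt_base": "A"
   },
   {
    "aa_label": "Q61",
    "assay_id": "KRAS_8",
    "codon_pos": 3,
    "codon_ref": "CAA",
    "gene": "KRAS",
    "kind": "simple",
    "mut_alleles": {
     "C": "Q61H",
     "T": "Q61H"
    },
    "primer_seq": "AGGTACTCCCTCCGTGATAA",
    "wt_base": "A"
   },
   {
    "aa_label": "G13",
    "assay_id": "NRAS_4",
    "codon_pos": 1,
    "codon_ref": "GGT",
    "complex_group": "NRAS_G13",
    "gene": "NRAS",
    "kind": "complex",
    "mut_alleles": {
     "A": "G13S",
     "C": "G13R",
     "T": "G13C"
    },
    "primer_seq": "CACCCCCAGGCTTAAATGATAAT",
    "wt_base": "G"
   },
   {
    "aa_label": "E545",
    "assay_id": "PIK3CA_6",
    "codon_pos": 1,
    "codon_ref": "GAG",
    "gene": "PIK3CA",
    "kind": "simple",
    "mut_alleles": {
     "A": "E545K"
    },
    "primer_seq": "GACGCCTACAGTCGCTAACCTACTGC",
    "wt_base": "G"
   }
  ],
  "W5": [
   {
    "aa_label": "G12",
    "assay_id": "KRAS_1",
    "codon_pos": 1,
    "codon_ref": "GGT",
    "complex_group": "KRAS_G12",
    "gene": "KRAS",
    "kind": "complex",
    "mut_alleles": {
     "A": "G12S",
     "C": "G12R",
     "T": "G12C"
    },
    "primer_seq": "GGGCGGGGTGTCTCAGG",
    "wt_base": "G"
   },
   {
    "aa_aliases": {
     "R970C": "R988C"
    },
    "aa_label": "R970",
    "assay_id": "MET_1",
    "codon_pos": 1,
    "codon_ref": "CGC",
    "gene": "MET",
    "kind": "simple",
    "mut_alleles": {
     "T": "R970C"
    },
    "primer_seq": "TGCAGGATTGATTGACGTGA",
    "wt_base": "C"
   },
   {
    "aa_label": "Q61",
    "assay_id": "NRAS_7",
    "codon_pos": 3,
    "codon_ref": "CAA",
    "gene": "NRAS",
    "kind": "simple",
    "mut_alleles": {
     "C": "Q61H",
     "T": "Q61H"
    },
    "primer_seq": "GTCGGAACGTAGAGGCGCGACAC",
    "wt_base": "A"
   },
   {
    "aa_label": "Q546",
    "assay_id": "PIK3CA_7",
    "codon_pos": 1,
    "codon_ref": "CAG",
    "gene": "PIK3CA",
    "kind": "simple",
    "mut_alleles": {
     "A": "Q546K"
    },
    "primer_seq": "ACACCTACGAGTATTGGATGGCATAG",
    "wt_base": "C"
   }
  ],
  "W6": [
   {
    "aa_label": "G12",
    "assay_id": "KRAS_2",
    "codon_pos": 2,
    "codon_ref": "GGT",
    "complex_group": "KRAS_G12",
    "gene": "KRAS",
    "kind": "complex",
    "mut_alleles": {
     "A": "G12D",
     "C": "G12A",
     "T": "G12V"
    },
    "primer_seq": "TCCGCTCCCGGGGTCATG",
    "wt_base": "G"
   },
   {
    "aa_aliases": {
     "T992I": "T1010I"
    },
    "aa_label": "T992",
    "assay_id": "MET_2",
    "codon_pos": 2,
    "codon_ref": "ACA",
    "gene": "MET",
    "kind": "simple",
    "mut_alleles": {
     "T": "T992I"
    },
    "primer_seq": "CCGCACCGTTAACGCGCTCGG",
    "wt_base": "C"
   },
   {
    "aa_label": "Q61",
    "assay_id": "NRAS_8",
    "codon_pos": 1,
    "codon_ref": "CAA",
    "gene": "NRAS",
    "kind": "simple",
    "mut_alleles": {
     "A": "Q61K",
     "G": "Q61E"
    },
    "primer_seq": "GCAAATAATATTCATCCCGCAATC",
    "wt_base": "C"
   },
   {
    "aa_label": "H701",
    "assay_id": "PIK3CA_8",
    "codon_pos": 2,
    "codon_ref": "CAT",
    "gene": "PIK3CA",
    "kind": "simple",
    "mut_alleles": {
     "C": "H701P"
    },
    "primer_seq": "TGGCTTGTAACCCGAGATCCCCCCCAA",
    "wt_base": "A"
   }
  ]
 }
}
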