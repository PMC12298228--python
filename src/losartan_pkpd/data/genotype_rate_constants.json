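{
  "version": 1,
  "k_m_per_cyp2c9": {
    "CYP2C9*1/CYP2C9*1": 2.817,
    "CYP2C9*3/CYP2C9*3": 0.039
  },
  "k_ent_int_per_abcb1": {
    "GG/CC": 151.485,
    "GT/CT": 101.8,
    "TT/TT": 1.431e-12
  },
  "abcb1_haplotype_aliases": {
    "CC/GG/CC": "GG/CC",
    "TT/TT/TT": "TT/TT"
  }
}
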