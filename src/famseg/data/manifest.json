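{
  "table1_recessive_variants.tsv": {
    "md5": "2d92d792bd7f312c580941046d539cbe",
    "n_rows": 85,
    "n_genes": 73
  },
  "table2_tumor_denovo_variants.tsv": {
    "md5": "203c80bdc2e45c23e6d4d03c06c3ad16",
    "n_rows": 15,
    "n_genes": 15
  }
}
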