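{
  "_comment": "Gapped Karlin-Altschul parameters (lambda, K) per substitution matrix and (gap_open, gap_extend), as reported by NCBI blastp for the same scheme. Used to convert raw Smith-Waterman scores to bit scores: bits = (lambda*raw - ln K) / ln 2.",
  "BLOSUM90": {
    "11,1": {"lambda": 0.302, "K": 0.093},
    "10,1": {"lambda": 0.29, "K": 0.075},
    "9,1": {"lambda": 0.265, "K": 0.048},
    "9,2": {"lambda": 0.31, "K": 0.12},
    "8,2": {"lambda": 0.3, "K": 0.099}
  },
  "BLOSUM62": {
    "11,1": {"lambda": 0.267, "K": 0.041},
    "10,1": {"lambda": 0.243, "K": 0.024}
  }
}
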