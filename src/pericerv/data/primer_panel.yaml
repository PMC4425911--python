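# PCR/qPCR primer and probe panel for the K111/K222 assays.
# Sequences are 5'->3'; whitespace in the published oligo listings removed.
primers:
  - {name: P1,                  seq: ACATTCAGACCATGGTAGCCGTGT,   role: forward}
  - {name: P2,                  seq: ACAGTGCTGTGTGGGTCTGAATGA,   role: reverse}
  - {name: P4,                  seq: GTACCTTCACCCTAGAGAAAAGCCT,  role: reverse}
  - {name: P9,                  seq: CAGGAGTGTTCTGGAATCCTATG,    role: forward}
  - {name: KLTR116-94R,         seq: AACAGAATCTCAAGGCAGAAGAA,    role: reverse}
  - {name: K111F,               seq: AAGAGCACCAGGATGCTTAATGCC,   role: forward}
  - {name: K111R,               seq: AGTGACATCCCGCTTACCATGTGA,   role: reverse}
  - {name: K111P,               seq: TGCCGGTCCTAACAGTAGACTCAC,   role: probe}
  - {name: K222F,               seq: CAGCGTTCTGGAATCCTATGT,      role: forward}
  - {name: K222R,               seq: TGTATTGTGGTAACTGGGTATATGT,  role: reverse}
  - {name: K222P,               seq: ACCCACATGGCAGTGTTCTGGATT,   role: probe}
  - {name: K222bR,              seq: GAAGCAGAGAGACTGCTTGTATAG,   role: reverse}
  - {name: K222LTR-pCER-D22Z8R, seq: TCCCTCACATAGGGTTGCCCCT,     role: reverse}
  - {name: 5SDNA-F1,            seq: CCGGACCCCAAAGGCGCACGCTGG,   role: forward}
  - {name: 5SDNA-R1,            seq: TGGCTGGCGTCTGTGGCACCCGCT,   role: reverse}
  - {name: 11-10F,              seq: AGTTTTTATGGGAAGACATTCCCT,   role: forward}
  - {name: Mcbox-3R,            seq: CGGGAATATCATCATCTAAAATCT,   role: reverse}
  - {name: GAPDHF,              seq: TGCACCACCAACTGCTTAGCACCC,   role: forward}
  - {name: GAPDHR,              seq: CTTGATGACATCATATTTGGCAGG,   role: reverse}
  - {name: TOP3AF,              seq: ACTAGGTCAGAGACCCTTACTG,     role: forward}
  - {name: TOP3AR,              seq: CAAGGAGAGGCAGTGACAAA,       role: reverse}
  - {name: 982R,                seq: GTACCTTCACCCTAGAGAAAAGCCT,  role: reverse}
  - {name: 1968R,               seq: TCCAGGTGGCATCGGTTCTAACAT,   role: reverse}
  - {name: 2499R,               seq: TTGAGCAACATCTTGGAGCCTTGC,   role: reverse}
  - {name: 3460R,               seq: ACTTGCCCAATATGCAGCCTTTCC,   role: reverse}
  - {name: 3500R,               seq: TAATGGCCTTACACACAGGTTTG,    role: reverse}
  - {name: 4734R,               seq: TGCCTAGAGTTGGCCGAATCCAAT,   role: reverse}
  - {name: 5388R,               seq: GACTGCAACCAACTCTGCTCTTTG,   role: reverse}
  - {name: 6609R,               seq: ATCCCTTCTTCCTCAGGTTTGGCA,   role: reverse}
  - {name: 7320R,               seq: TCCTAATGTGGTATGAGGCTGCAGT,  role: reverse}
  - {name: 1965F,               seq: ATGGAACCGATGCCACCTGGA,      role: forward}
  - {name: 2641F,               seq: AAAGCCTGTGATGGAATCGGAGGA,   role: forward}
  - {name: 3170F,               seq: TTCCCCTGCCACAAGCTGC,        role: forward}
  - {name: 4080F,               seq: TCTCGCCTTGGAATTCTCCTGTGT,   role: forward}
  - {name: 5359F,               seq: TCGGCTCAAAGAGCAGAGATGGTT,   role: forward}
  - {name: 6586F,               seq: TGCCAAACCTGAGGAAGAAGGGAT,   role: forward}
  - {name: 7972F,               seq: AAATTTGGTGCCAGGAACTGAGGC,   role: forward}
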