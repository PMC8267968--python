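>synthetic_human_lrat_cds
ATGAAGAACTCCATGCAGTTCCAACTATCTTACCCTTTCACGGCTCGAGGAAATATGGTTAGAGATCAAG
TGCCATCTCGGGGTCCACATAGAACGTTCCCAGCCTTTCAGGCATCTTTGGTTGATGCTTGGGGGAGAGT
TTATACTTCTCAAGCTACTCTTGTGTATAGTTTAAGCGAGTTAAGACCCAGATCGTCACGGGCACCATTC
CTAAGCTATCGCGGTAAAGATGATAGAGAAAAGATGTACATAGAACTACCGTTACCTGGGACCGGAGGCT
GTATATACTGTCCACGCGTCCTCCCCGTAAACCCGAACTGGTGGGTCGGTGTAACTCGAAACTGCTTTTG
CATGTGGAACACTGGCAGGGCACTGCACTCCCAGATCTCTGCACCAAATATTAGCGGGACTTTCCCTGGT
AGAGATAATACGTGGGCTCCGAAGAGCCTCGCAGAGTTGTACTATTGGACACGCTCATGGCAAGCACCAC
CTCCATTGGACTATTCCCGCGCTCAAAACGTGTTACAAACCGGTGAACTTAGTTCTAGCAGCAAGAGCAT
TCAGGTCGGTAATCAGATACTAGCGTCTAAGTCTGAGGTCAAACGGCCACCGTATGCTGTTTGTCCTGAA
TTAATGACAGGGCCAGGGCAGTCAAGCAAGTCTCTGGGTCGTTGTTTGAGCGAGAACTCCTAA
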