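>synthetic_rat_lrat_cds
ATGAAGAACTCAATGCTGGAGGCTGCGTCCCTCCTTCTGGAGAAGCTGCTCCTTATTTCTTTCGTGGCCA
CACAAGGGCAAGGGCAACCACACATGGGCATATACAGGGGTGAATCAAGGCTACCTCTTGACCGGTCCTG
TGAGTCCAAGTCGTACAATCACTGCTGTAACGATGACAGCAACTTCAGAGCGCATGAGGATCTCTCAAAA
GCCGCCCTAAGGGAAACTGTTTGTAGCGAAGGACTTCGTGTGATCGTGGCATTTCGTACGCTTTACCCAA
TCGGCGGAGAAGTACTCCGTGATTACCATCTACCTCCCCCATTCCCGCAGTCCGATGTGAACCGCAGGCC
GTTTCCGGCCGTCATGGAGTTAAGATCGGCGCGTAGCGTGATGCTGTACTATCTCGCATGCGTTCGCCGA
GTATGGTGCATAGCGGTTGTAGTCTCATTCAGGCTGCAGGACACACCGTTAAGGTCGGTGAGCCGAGCCA
GCTACCTACTTAACTTAGAGCAATTTTTTGTGCTTCCGTTAACAAGGCATAACATTAACTGGGCCGAGCG
CAGCCGACGTTTATTAATCGGTTCTAAGATAGGTAGAATGTTCCCTCAAGAGGGTATGACCTGCGAAAAG
GACCTTGGCGGTTTAAAAATATATGCGCGCCAATCGCTATCTTGTCACTTTACACGGTACTAA
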