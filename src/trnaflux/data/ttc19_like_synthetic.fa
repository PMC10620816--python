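>TTC19_LIKE_SYNTHETIC synthetic demonstration CDS (not the real human TTC19 sequence); 380 codons, exactly 13 GCT
ATGGTCGCTTCAGCTGTCCTCACTACAGGCCCGTTTGCAAACGGAATATCAAGCGCTCAG
CGAGCCGTCCATTTCATTCCTCTTTTTTCCGGAGAACGTAGTGAGCCCACGGGTAAAAGC
GGGCCTCTCATTTTAGCTTATGTACCACCGAAGACGATAGCTGTGTTAAGGTCAGAGTGT
GAGGTGAAGGTCTATTCATATCGACCACTCGGGAATGTGCACAGCTACCGCAACTGTGCG
CAATTTCAGCAAGAGTTTATACAAACACTAGGACGTCGCTCCGACATGCCGCGCCACGGC
ATGCTGGTTCGGCCAACTCTGGGACTGGCTTTTTGGGCTGTACCTAAAACTGTGCTTTGG
ATTTCGCTTATCCAAGCACACAACCGAGGTTCTACCGCGGCTATTTGCACTCAAGTACTG
TGCGACACTGTGTGTGCGAAGCCGGGTCCTGACGTCCGCAACATTATGGAGCTGGTCGTC
GGGAGGAACCGTGTCGACTCCTACTTGGCAGCAATTACCTTAAAATCTCTCAATATCCCG
AGAAATTCTAGGAAACTCGATCCAGCCTTCACAAAATGCTCGGTCAAACAGCTCCACGGC
ATCTGTGGACGGAGGGTAGCTGTAAACAGACACGACCATCCACACCTGAATTGCTCCAGC
GAGGGCTCCCTCCAATGGCACTGCGGGCAAGCTTCTCCAAGACTAATTCCTTGCTGGATA
ATCTCCTGTCTTCCGACCTGGACACAGATATCTCCGTCCAGCGAGAACGTCGCCACCCCG
TCGCCAGTTTGCTATGCCGGTAAGACAGAAGAACGACGATTCCAAGCTAAGGATACGCCG
CTGACTTGCGTTATCTATCGTTTAAAGGAGCTGAGCTTTGTCTGTCAAAAAGTTAGTCAC
AGCCACAGCTACATGTACACCGGACCGCTAATCTCGCCACCAGGAGTTGAAGTAGATACC
AGGTTTACAGAAGAGCAAAATGTTGGCGTCTGCGAGCGCGTATTCAACAAACGGATGTTC
GGGGATTTGATAGTCGAAATGAGACGAAGATGGGGATGCCGCCTCCCGCTATGTTGGGCT
CCTGCCGCTAGGTTCTTACATCTAGAGGTTTACACTACCTTGGTCATTCGCATGCAGAGT
TAA
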