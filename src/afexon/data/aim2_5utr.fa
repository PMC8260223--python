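>Aim2_5UTR_annotated RefSeq-annotated Aim2 5'UTR (mouse)
TTCCTGTCCTGTCTGCCGCCATGCTTCCTTAACTAGCTGCTAGGTTTTTTCCTTGTCGTG
ATGAAATCCACCCTCATGGACCTGTAAGTAAAATGTAGACTTGCATAGAGTGCTGTAATC
TTACGGCCGAGGTTTCTTTTCAGGCTGATCCTGGGACTGTGAG
>Aim2_5UTR_unannotated inflammatory-regulated unannotated Aim2 5'UTR (mouse)
TATATCTAAAATACCTCTGGTTGAGACCTCACAGCTGGAGGAGAAACTCTGCTGAGGCTT
GTAAAAAGGAAACTGAAAACTAGCATTTGCTTGGGCAGAGCCTTAATATATAATTATTTT
GCCCCAGCATCAGGGTTTAGGACTCAGCTATAGGGCCAGGACTAGCCAAGCTTCAAAGTG
AAAGAAGATAGTTGAGAGTACTTTCTGCTTTCTGTCTCCCAAGACCTGATTTTCATGATT
TTCATGTCCTACTACTCATAGTGAAAATCTTTGTGAGGCGGATGGTTTGAACTCTCAGGA
CATACACCAGTCCCTGAGTTGAGAACTAAGGCTGCTTTGGAGAGAAGAAAATCCCCTGAG
GTAAGTAGACTTGCATAGAGTGCTGTAATCTTACGGCCGAGGTTTCTTTTCAGGCTGATC
CTGGGACTGTGAG
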