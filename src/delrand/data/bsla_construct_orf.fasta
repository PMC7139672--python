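>pelB-BSLA_orf coding ORF incl. stop codon
ATGGGCAAATATCTGCTGCCGACCGCAGCAGCGGGTCTGCTGCTGCTGGCAGCACAGCCTGCACATATGG
CAGAACATAATCCGGTTGTTATGGTTCATGGTATTGGTGGTGCAAGCTTTAACTTTGCAGGCATTAAAAG
CTATCTGGTTAGCCAAGGTTGGAGCCGTGATAAACTGTATGCAGTTGATTTTTGGGATAAAACCGGCACC
AATTATAACAATGGTCCGGTTCTGAGCCGTTTTGTTCAGAAAGTTCTGGATGAAACCGGTGCCAAAAAAG
TTGATATTGTTGCACATAGCATGGGTGGTGCGAATACCCTGTATTACATTAAAAACCTGGATGGTGGTAA
CAAAGTTGCCAATGTTGTTACCTTAGGTGGTGCCAATCGTCTGACCACCGGTAAAGCACTGCCTGGCACC
GATCCGAATCAGAAAATTCTGTATACCAGCATTTATAGCAGCGCAGATATGATCGTGATGAATTATCTGA
GTCGTCTGGATGGCGCACGTAATGTTCAGATTCATGGTGTGGGTCATATTGGTCTGCTGTATAGCAGCCA
GGTTAATAGCCTGATTAAAGAAGGTCTGAACGGCGGAGGTCAGAATACCAATTAA
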