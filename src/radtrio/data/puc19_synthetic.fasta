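>pUC19_synthetic circular synthetic stand-in for GenBank L09137; planted GAATTC@396 TCTAGA@423 and pUC19-215F/774R primer sites
ATTGTCCACCTTCTTGATTCCACTAGAGAAGAACACGTTCTTCTGCTTGAACCTCTTGCTCATCGCCTAT
CCGGATCTGCTGAAACAAAGTTCGATCACTAGCCTTTAATAAAGAGGGCGATCTGCATTGAGACAACGGC
ACTCGTGGTAGTGCTATGGTCGCGCGCTTTCCGTCGGACATGTAGCGGCAACGTTGTAAAGTGTAGTGCG
TAGGAAGGAGAAAATACCGCATCAGGTTCGACACTTATGGAGAGCGCTTCAGCTTCTTCCCGCAGAAGTT
TGGTGCCCCGTCATAGTAACGCAACGTTGACAAAAGTGTGAGACTCGACACCGCATCTATATTGAAAGCC
TTTAAGTTCCATAATTCAGATTGCGGATCTACTGCCTGGGCTGTTGAATTCGATTTGCCACCAGTCTATT
CGTCTAGAGAGCTTAGCCAGGCACTAGCGACGACGAGGGGAAATGTGACCCTGCATGGATATCAAGCGCC
AACTTAAACCCAAAAGTACTACGGCATGAGTACTAATTTTAGTGGATCAGACATTTCCCTACTATAGGAT
AGACGTAGGATAGGGAATATTCTGAGTTATGGACCAAATGGTTGGCTGCTGTCATAACAGGGATCCCGCC
ACCTGAATCTCGGGCGGGTCGTATTCTGCGAGTGACGTGTGATCTCACGCTGAATTGCTTGTCCCTTCCC
ATTAGACAAAGAATTGCGAATGGAGTCACAGAGTACGTCCGGCGCCAGGGGTCTCAAAGGCGGTAATACG
GTTATAGACGGGGGGGGTTATCGCAAAAGATTAGGTTTAAGGACCCCCCTAAACGCGGTCTCGACTTCTT
CTGTGTTGGGGATGAACCGAGACGCAAGCCCCAAGACCGATTAAGGTGAAGAACATGGCCAACGGACCCT
CGGCCTGTATACTGAATACACTATCCACGAGAACCTGGCGGGTTAAGGGGGGCTGAGGATCGCAGGGTGG
AACATATTGTGCCGTGTTGTCGACAGAAATTGCCTTAGTTAGGTGGACAAGGGGCCCCCGCTCCGTCGGC
CCACCGGCCATAGCCTATGGTATCAGAAGTCTTAACGGAGGGGCAAGTAAACGGCCCTTCCGCTAATCCA
GGTCAGTTGCGCGGAACATGTAACAAATTAGAGATCCCATGTTGAACACGGTATGAGGAGGTGGAAAACA
AATTTCCTAGACGCTGGTATCTGAACGCCCTGCCCTGACTGATTAACAAGCGAAAGCGAACTGAACTCCC
TGCTTGCGCTCGGTCTGTTCTTTGCTGTTATATTCACGGGAGCCCGGCGTAGTCTGCGTGGCGGGGCGCA
AAGTGCGACGGAGACCCATAAGGGCCCAGTGCTTACTCCCTGATGTCATATTCAATGTAGGCGGACCGAG
TTCCGTAAGCTCGCTGGATTCCCTCAAAAGCTACTTGCAGAATACTTAGCGTGTGGGTACACGCGATGAA
TAAAACCTCTTCTCGATGAGCCACGCTGGGTAACGTATGAGTTCTGCAACCTGAAATATATTCACTACAA
GCGTGACTTCCAAGAAACCACCTGGAATAGTTAAAGAGCACAACGGTGGGTTCAAGCGGATCTCACGGGA
CGGGCGTCCCGATAGCCGTGCGCAAAACTGAAGCCAACGGTACGTGCAGGGCTTCGAAAGGAATCGCGGA
AAATAGGCTGTACATACACATTCCTCGAATTTTAGGCCTCTTGCAATGTTGCGCTCGAGCGCGTCCTTAA
AAAGTAATATGTATACAAGTAGAGGACCCGTTTCCCAAATCGGCCGGGCCATATAGGATCTGTCCGAGCA
CAATGGTATCCGTATAAGGCTCTCACGGTTCTCATACCGCATACTGACACAAATGGAACTGACGTAGCAT
TATACACGACAAAAATGCTGTCAGTGCTGTGAGGGATCAATGGAGCTGAATCTAAAGCCGCTGGTCCTTT
AAGAGTGGTTCTTGACATAGGACCCCGTAGGTATCTACGCTGACCACTGCTTAATTCCTGCTGTTGCACC
CCAGCGGGGTTTAGGGTCCGGCTGCGAACCCGTCCAGTACTCAGCGACTCACGAGACTACCAACCCACTT
CCATATTCCCGTATGTGCCAGAGGTGCACTGTATTCCATAAAGTCGATATCGTGTTCAAGGTCCCAGCAG
CAGGGTTACCGGTTCGAGGTTATCCATATTGTGGCGGGTCAGTCGGGCGCGGGGGCAACCTGAGGAAGTT
TTAGGCCATAACAGCGGAAGCGAACTCGTTATACAGTGAACTCTAGCCCGCACTCCTCCACCTGTTGTTC
AGCTGACCTCCCACTGACCTATACATCGAATGCGCTTCGCCATCACTTGAAGCTGAAATTATTGTCACTA
CACCGTTACTATTGCTTTACAAAAATATACCCCGTGAGTCTTGTTTGCACTGTGCAGGTCGTGAGTCTAG
GCGTGTCCTGGTTGCGTCCGTCCAGGCCTGTGTGCATTTTCGCGCATTGATTTCCTTCACTGGCGACTGC
AAACGAAGGAACTCGCCATAAAAGACATGACTCCTCGACATGGTTTCTATTAAGCGTCATAAGCCGTACG
GAGCTTCCCGCCATCTAATAGTATACGGACATCAGTCCAGCTGCGCTGTCCAACTTTGTGGTTAAGTGAA
GGTCAGGGCCTTGTTGACGCATCGAG
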