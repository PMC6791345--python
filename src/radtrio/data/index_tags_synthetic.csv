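set,side,version,tag,design_override
universal,r1,A,CCGAAT,
universal,r1,B,TTAGGCA,
universal,r1,C,AACTCGTC,
universal,r1,D,GGTCTACGT,
universal,r1,E,GCGGTA,
universal,r1,F,AACCTTG,
universal,r1,G,CGCAGTTC,
universal,r1,H,GCCAGCGCC,
universal,r2,1,CTAACG,
universal,r2,2,TCGGTAC,
universal,r2,3,GATCGTTG,
universal,r2,4,AGCTACACT,
universal,r2,5,AGGATC,
universal,r2,6,ACAGACC,
universal,r2,7,TGGGCATC,
universal,r2,8,ATCAACGGG,
universal,r2,9,TACTCC,
universal,r2,10,TATCCTT,
universal,r2,11,GGCACAAG,
universal,r2,12,CGGTATTAG,
universal,r2,5,TCATCT,2
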