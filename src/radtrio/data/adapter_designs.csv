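design_id,side,adapter_name,enzyme,top_prefix,top_suffix,bottom_prefix,bottom_suffix,tail
1,read1,iTru_NheI_R1,NheI,ACGACGCTCTTCCGATCT,G,CTAGC,AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT,
1,read2,iTru_EcoRI_R2,EcoRI-HF,AATTA,AGATCGGAAGAGCACACGT,GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT,T,aatcc
2,read1,iTru_ClaI_R1,ClaI,ACGACGCTCTTCCGATCT,AT,CGAT,AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT,
2,read2,iTru_BamHI_R2,BamHI-HF,GATCG,AGATCGGAAGAGCACACGT,GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT,C,aatcc
3,read1,iTru_PstI_R1,PstI,ACGACGCTCTTCCGATCT,CTGCA,G,AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT,
3,read2,iTru_DdeI_R2,DdeI,TNAC,AGATCGGAAGAGCACACGT,GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT,G,aatcc
4,read1,iTru_CviQI_R1,CviQI,ACGACGCTCTTCCGATCT,G,TAC,AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT,
4,read2,iTru_HindIII_R2,HindIII,AGCTA,AGATCGGAAGAGCACACGT,GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT,T,aatcc
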