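name,side,sequence
iTru5_01,i5,CTACAGCA
iTru5_02,i5,CGCGATTT
iTru5_03,i5,CGCAGGTC
iTru5_04,i5,ATTCAGGA
iTru5_05,i5,TCGGGTTA
iTru5_06,i5,GCCCGCAG
iTru5_07,i5,CGACACGG
iTru5_08,i5,CGCCTTAG
iTru7_01,i7,CTGCCAAT
iTru7_02,i7,ACTCCGTT
iTru7_03,i7,GTTAGGCT
iTru7_04,i7,TCTGAGGG
iTru7_05,i7,TACCCAAT
iTru7_06,i7,GTATGCTA
iTru7_07,i7,CTAGGAGC
iTru7_08,i7,AAAAAGGG
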