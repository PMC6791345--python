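name	recognition	cut_top	cut_bottom	temp_C	buf_2_1	buf_3_1	buf_cutsmart	meth_sensitive	role	design_set	warning
NheI	GCTAGC	1	5	37	100	10	100	+/-	read1_blocking	R1.A
XbaI	TCTAGA	1	5	37	100	75	100	-	read1_primary	R1.A
SpeI	ACTAGT	1	5	37	100	25	100	-	read1_primary	R1.A
ClaI	ATCGAT	2	4	37	50	50	100	+	read1_blocking	R1.B
MspI	CCGG	1	3	37	100	50	100	-	read1_primary	R1.B
TaqaI	TCGA	1	3	65	75	100	100	-	read1_primary	R1.B
PstI-HF	CTGCAG	5	1	37	75	50	100	-	read1_blocking	R1.C
PstI	CTGCAG	5	1	37	75	100	50	-	read1_blocking	R1.C
NsiI	ATGCAT	5	1	37	75	100	25	-	read1_primary	R1.C
CviQI	GTAC	1	3	25	100	100	75	-	read1_blocking	R1.D
NdeI	CATATG	2	4	37	100	100	100	-	read1_primary	R1.D
MseI	TTAA	1	3	37	100	75	100	-	read1_primary	R1.D
AseI	ATTAAT	2	4	37	50	100	10	-	read1_primary	R1.D
BfaI	CTAG	1	3	37	10	10	100	-	read1_primary	R1.D
EcoRI-HF	GAATTC	1	5	37	100	10	100	+/-	read2	R2.1
MfeI-HF	CAATTG	1	5	37	25	10	100	-	read2	R2.1
ApoI	RAATTY	1	5	50	75	100	75	-	read2	R2.1
BamHI-HF	GGATCC	1	5	37	50	10	100	-	read2	R2.2
BclI	TGATCA	1	5	50	100	100	75	-	read2	R2.2
BstYI	RGATCY	1	5	60	100	75	100	-	read2	R2.2
DdeI	CTNAG	1	4	37	100	100	100	-	read2	R2.3
HindII-HF	GTYRAC	3	3	37	100	10	100	-	read2	R2.4	listed as HindII-HF; blunt cutter, likely HindIII-HF; recorded verbatim
HindIII	AAGCTT	1	5	37	100	50	50	-	read2	R2.4
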