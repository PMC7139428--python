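gene	accession	forward	reverse	product_size
Nr3c1	NM_012576.2	AGGCGATACCAGGCTTCAGA	TCAGGAGCAAAGCAGAGCAG	142
Jazf1	XM_001065610.6	CCAACAGGCAGCGAGTATGA	AGGCTTCTCTTCCCCTCCAT	138
Rap2c	NM_001106950.2	GGCCATACCGAGCAGATAAAAAC	TGGATCTGGAGGGCCAAAGA	164
Zkscan1	NM_001025760.1	GGAGTCCTCAAGCTTCGACC	GATCTTCACCATTGCCTGGGA	193
Pank3	NM_001108272.2	TGGGCTGTGGCATCTAGTTTT	AACAGCACACATTCGAGCCA	135
HPRT	NM_012583.2	GTCCTGTTGATGTGGCCAGT	TGCAAATCAAAAGGGACGCA	144
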