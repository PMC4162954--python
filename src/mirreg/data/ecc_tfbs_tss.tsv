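#coords=0
precursor_id	chrom	position	strand	source
hsa-mir-9-2	chrE	100000	+	mirna_tss
hsa-mir-181a-2	chrE	200000	-	mirna_tss
hsa-mir-424	chrE	300000	+	mirna_tss
hsa-mir-301a	chrE	400000	-	mirna_tss
hsa-mir-182	chrE	500000	+	mirna_tss
hsa-mir-942	chrE	600000	-	mirna_tss
hsa-mir-183	chrE	700000	+	mirna_tss
hsa-mir-135b	chrE	800000	-	mirna_tss
hsa-mir-766	chrE	900000	+	mirna_tss
hsa-mir-19b-2	chrE	1000000	-	mirna_tss
hsa-mir-22	chrE	1100000	+	mirna_tss
hsa-mir-324	chrE	1200000	-	mirna_tss
hsa-mir-124-2	chrE	1300000	+	mirna_tss
hsa-mir-7-1/7-3	chrE	1400000	-	mirna_tss
hsa-mir-577	chrE	1500000	+	mirna_tss
hsa-mir-1251	chrE	1600000	-	mirna_tss
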