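cell_line	mature_id	fold_change	gene_id	confidence	validated
2102Ep	miR-148a	-3.63	ARRDC3	high	1
2102Ep	miR-148a	-3.63	ATP2B4	high	0
2102Ep	miR-148a	-3.63	CHD7	high	0
2102Ep	miR-148a	-3.63	ELMO1	high	0
2102Ep	miR-148a	-3.63	FAM123B	high	0
2102Ep	miR-148a	-3.63	H2AFY	high	0
2102Ep	miR-148a	-3.63	HDGF	high	0
2102Ep	miR-148a	-3.63	HMGA2	standard	0
2102Ep	miR-148a	-3.63	IL6ST	high	0
2102Ep	miR-148a	-3.63	ITGA5	high	1
2102Ep	miR-148a	-3.63	ITGB8	standard	1
2102Ep	miR-148a	-3.63	LIX1	high	0
2102Ep	miR-148a	-3.63	NRP1	high	0
2102Ep	miR-148a	-3.63	PREX1	high	0
2102Ep	miR-148a	-3.63	TEAD1	standard	0
2102Ep	miR-148a	-3.63	TMEM54	high	0
2102Ep	miR-26a	-1.73	ADAM19	high	0
2102Ep	miR-26a	-1.73	AMOT	high	0
2102Ep	miR-26a	-1.73	CDH2	high	0
2102Ep	miR-26a	-1.73	CDH11	high	0
2102Ep	miR-26a	-1.73	CSNK1G1	high	0
2102Ep	miR-26a	-1.73	ENC1	high	0
2102Ep	miR-26a	-1.73	ENPEP	high	0
2102Ep	miR-26a	-1.73	HAS2	high	0
2102Ep	miR-26a	-1.73	HMGA2	high	1
2102Ep	miR-26a	-1.73	HOXA5	high	1
2102Ep	miR-26a	-1.73	HOXA9	high	0
2102Ep	miR-26a	-1.73	LHX1	standard	0
2102Ep	miR-26a	-1.73	ITGA5	high	0
2102Ep	miR-26a	-1.73	ITGB8	high	0
2102Ep	miR-26a	-1.73	LEF1	high	1
2102Ep	miR-26a	-1.73	LIFR	standard	0
2102Ep	miR-26a	-1.73	MAP2	high	1
2102Ep	miR-26a	-1.73	NID1	high	0
2102Ep	miR-26a	-1.73	NRIP1	high	0
2102Ep	miR-26a	-1.73	PLXNA2	high	0
2102Ep	miR-26a	-1.73	PRTG	standard	0
2102Ep	miR-26a	-1.73	SSFA2	high	0
2102Ep	miR-26a	-1.73	TFAP2A	high	0
2102Ep	miR-26a	-1.73	USP3	high	0
2102Ep	miR-26a	-1.73	WNT5A	high	0
2102Ep	miR-26a	-1.73	ZSWIM6	high	0
2102Ep	miR-200b	-1.48	AHNAK	standard	0
2102Ep	miR-200b	-1.48	ARRDC3	high	0
2102Ep	miR-200b	-1.48	CDH11	high	0
2102Ep	miR-200b	-1.48	CNKSR3	high	0
2102Ep	miR-200b	-1.48	CNTFR	high	0
2102Ep	miR-200b	-1.48	EFNA1	high	1
2102Ep	miR-200b	-1.48	EMP1	standard	0
2102Ep	miR-200b	-1.48	FN1	high	1
2102Ep	miR-200b	-1.48	GATA2	high	1
2102Ep	miR-200b	-1.48	GLI3	high	0
2102Ep	miR-200b	-1.48	HEG1	high	0
2102Ep	miR-200b	-1.48	HOXA5	high	0
2102Ep	miR-200b	-1.48	KIAA0101	high	0
2102Ep	miR-200b	-1.48	MAP2	high	0
2102Ep	miR-200b	-1.48	MBNL3	standard	0
2102Ep	miR-200b	-1.48	NKD1	high	0
2102Ep	miR-200b	-1.48	NRIP1	high	0
2102Ep	miR-200b	-1.48	NRP2	high	0
2102Ep	miR-200b	-1.48	NTF3	high	0
2102Ep	miR-200b	-1.48	PLXNA2	high	0
2102Ep	miR-200b	-1.48	PRTG	high	0
2102Ep	miR-200b	-1.48	ST6GALNAC5	high	0
2102Ep	miR-200b	-1.48	TEAD1	standard	0
2102Ep	miR-200b	-1.48	TFAP2A	high	1
2102Ep	miR-200b	-1.48	WWC3	high	0
2102Ep	miR-200b	-1.48	ZEB2	high	1
2102Ep	miR-30c	-1.23	ACTC1	high	0
2102Ep	miR-30c	-1.23	ADAM19	high	0
2102Ep	miR-30c	-1.23	ADAMTS9	high	0
2102Ep	miR-30c	-1.23	AHNAK	high	0
2102Ep	miR-30c	-1.23	CAMK2N1	high	0
2102Ep	miR-30c	-1.23	CHD7	standard	0
2102Ep	miR-30c	-1.23	CSNK1G1	high	0
2102Ep	miR-30c	-1.23	CYP24A1	high	0
2102Ep	miR-30c	-1.23	ELMO1	high	0
2102Ep	miR-30c	-1.23	FAM123B	high	0
2102Ep	miR-30c	-1.23	GRHL2	high	0
2102Ep	miR-30c	-1.23	ITGA5	high	0
2102Ep	miR-30c	-1.23	KIAA1024	high	0
2102Ep	miR-30c	-1.23	LHX1	standard	0
2102Ep	miR-30c	-1.23	LIFR	high	0
2102Ep	miR-30c	-1.23	MBNL3	high	0
2102Ep	miR-30c	-1.23	NID1	high	0
2102Ep	miR-30c	-1.23	NRIP1	high	0
2102Ep	miR-30c	-1.23	NRP2	standard	0
2102Ep	miR-30c	-1.23	PLXNA2	high	0
2102Ep	miR-30c	-1.23	PRTG	standard	0
2102Ep	miR-30c	-1.23	RARG	high	0
2102Ep	miR-30c	-1.23	RASGRP3	high	0
2102Ep	miR-30c	-1.23	RHOB	high	0
2102Ep	miR-30c	-1.23	SNAI1	high	1
2102Ep	miR-30c	-1.23	SNAI2	high	0
2102Ep	miR-30c	-1.23	TBL1X	high	0
2102Ep	miR-30c	-1.23	TEAD1	standard	0
2102Ep	miR-30c	-1.23	TIMP3	high	0
2102Ep	miR-30c	-1.23	ZEB2	high	0
2102Ep	miR-30c	-1.23	ZSWIM6	high	0
2102Ep	miR-28	1.71	DPF1	standard	0
2102Ep	miR-28	1.71	IQSEC2	high	0
2102Ep	miR-28	1.71	PRUNE2	high	0
2102Ep	miR-517b	-1.94	CACNG4	standard	0
2102Ep	miR-517b	-1.94	HOXA5	high	0
2102Ep	miR-517b	-1.94	NKD1	standard	0
2102Ep	miR-517b	-1.94	PRTG	standard	0
2102Ep	miR-517b	-1.94	ZEB2	standard	0
2102Ep	miR-517b	-1.94	ZNF436	standard	0
2102Ep	miR-518a-3p	-2.47	FRAS1	standard	0
2102Ep	miR-518a-3p	-2.47	IL13RA1	standard	0
2102Ep	miR-518a-3p	-2.47	TEAD1	standard	0
2102Ep	miR-518a-3p	-2.47	TGFBR3	standard	0
2102Ep	miR-518b	-2.06	FRAS1	standard	0
2102Ep	miR-518b	-2.06	IL13RA1	standard	0
2102Ep	miR-518b	-2.06	TEAD1	standard	0
2102Ep	miR-518b	-2.06	TGFBR3	standard	0
2102Ep	miR-518c	-3.33	FRAS1	standard	0
2102Ep	miR-518c	-3.33	IL13RA1	standard	0
2102Ep	miR-518c	-3.33	TEAD1	standard	0
2102Ep	miR-518c	-3.33	TGFBR3	standard	0
2102Ep	miR-518f	-1.87	FRAS1	standard	0
2102Ep	miR-518f	-1.87	IL13RA1	standard	0
2102Ep	miR-518f	-1.87	TEAD1	standard	0
2102Ep	miR-518f	-1.87	TGFBR3	standard	0
NTera-2	miR-200c	-1.80	AHNAK	high	0
NTera-2	miR-200c	-1.80	CITED2	high	0
NTera-2	miR-200c	-1.80	MBNL3	standard	0
NTera-2	miR-200c	-1.80	NTF3	high	1
NTera-2	miR-200c	-1.80	PLXNA2	high	0
NTera-2	miR-200c	-1.80	PRTG	high	0
NTera-2	miR-200c	-1.80	SEMA6D	high	1
NTera-2	miR-200c	-1.80	YPEL2	high	0
NTera-2	miR-367	-1.46	ATP2B4	high	0
NTera-2	miR-367	-1.46	CADM2	high	0
NTera-2	miR-367	-1.46	EOMES	high	0
NTera-2	miR-367	-1.46	HAND1	high	0
NTera-2	miR-367	-1.46	MBNL3	standard	0
NTera-2	miR-367	-1.46	PKDCC	standard	0
NTera-2	miR-367	-1.46	SEMA6D	standard	0
NTera-2	miR-367	-1.46	SESN3	high	0
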