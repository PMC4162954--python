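feature_id	feature_kind	cell_line	fold_change	p_value	fdr
miR-9*	mirna	2102Ep	5.16	0.01	
miR-9	mirna	2102Ep	3.83	0.01	
miR-181a-2*	mirna	2102Ep	3.05	0.01	
miR-424	mirna	2102Ep	2.87	0.01	
miR-301	mirna	2102Ep	1.78	0.01	
miR-182	mirna	2102Ep	-2.08	0.01	
miR-942	mirna	2102Ep	-2.10	0.01	
miR-183*	mirna	2102Ep	-2.32	0.01	
miR-183	mirna	2102Ep	-2.90	0.01	
miR-135b*	mirna	2102Ep	-3.04	0.01	
miR-766	mirna	2102Ep	-5.04	0.01	
miR-19b	mirna	NTera-2	-1.35	0.01	
miR-22	mirna	NTera-2	-1.58	0.01	
miR-324-5p	mirna	NTera-2	-1.91	0.01	
miR-124	mirna	NTera-2	-1.98	0.01	
miR-22*	mirna	NTera-2	-2.02	0.01	
miR-7	mirna	NTera-2	-2.27	0.01	
miR-135b*	mirna	NTera-2	-2.33	0.01	
miR-135b	mirna	NTera-2	-2.56	0.01	
miR-181a	mirna	NTera-2	-2.61	0.01	
miR-577	mirna	NTera-2	-3.31	0.01	
miR-181a-2*	mirna	NTera-2	-4.47	0.01	
miR-1251	mirna	NTera-2	-7.90	0.01	
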