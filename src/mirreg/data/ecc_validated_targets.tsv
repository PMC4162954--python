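mirna_id	gene_id	evidence
miR-9	CDX2	reporter assay
miR-9	ID2	reporter assay
miR-182	RARG	reporter assay
miR-182	SNAI2	reporter assay
miR-183	SNAI2	reporter assay
miR-19b	PRUNE2	reporter assay
miR-324-5p	AHNAK	reporter assay
miR-181a	NANOG	reporter assay
miR-9*	SOX2	reporter assay
miR-145	SOX2	western blot
miR-126	SOX2	qpcr
miR-148a	HMGA2	microarray
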