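precursor_id	mature_id
hsa-mir-9-2	miR-9*
hsa-mir-9-2	miR-9
hsa-mir-181a-2	miR-181a-2*
hsa-mir-181a-2	miR-181a
hsa-mir-424	miR-424
hsa-mir-301a	miR-301
hsa-mir-182	miR-182
hsa-mir-942	miR-942
hsa-mir-183	miR-183*
hsa-mir-183	miR-183
hsa-mir-135b	miR-135b*
hsa-mir-135b	miR-135b
hsa-mir-766	miR-766
hsa-mir-19b-2	miR-19b
hsa-mir-22	miR-22
hsa-mir-22	miR-22*
hsa-mir-324	miR-324-5p
hsa-mir-124-2	miR-124
hsa-mir-7-1/7-3	miR-7
hsa-mir-577	miR-577
hsa-mir-1251	miR-1251
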