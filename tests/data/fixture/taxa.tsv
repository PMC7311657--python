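accession	species	subspecies	cluster
grpA_001	sp. one	one	grpA
grpA_002	sp. one	one	grpA
grpA_003	sp. one	one	grpA
grpA_004	sp. one	one	grpA
grpB_001	sp. two	two	grpB
grpB_002	sp. two	two	grpB
grpB_003	sp. two	two	grpB
grpB_004	sp. two	two	grpB
grpC_001	sp. three	three	grpC
grpC_002	sp. three	three	grpC
grpC_003	sp. three	three	grpC
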