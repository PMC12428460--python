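mirna_id	target_gene	evidence
hsa-miR-16-5p	CHEK1	validated
hsa-miR-16-5p	PIM1	validated
hsa-miR-124-3p	PIM1	validated
hsa-miR-193b-3p	CHEK1	validated
hsa-miR-195-5p	CHEK1	validated
hsa-miR-195-5p	PIM1	validated
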