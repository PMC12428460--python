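circ_id	mirna_id	n_sites	agoclip_p_bound
hsa_circ_0024791	hsa-miR-16-5p	1	≤10^−6
hsa_circ_0024793	hsa-miR-16-5p	2	≤10^−6
hsa_circ_0024794	hsa-miR-16-5p	1	≤10^−6
hsa_circ_0076213	hsa-miR-16-5p	2	≤10^−12
hsa_circ_0076214	hsa-miR-16-5p	1	≤10^−12
hsa_circ_0076215	hsa-miR-16-5p	2	≤10^−12
hsa_circ_0076216	hsa-miR-16-5p	2	≤10^−12
hsa_circ_0076213	hsa-miR-124-3p	1	≤10^−12
hsa_circ_0076214	hsa-miR-124-3p	1	≤10^−12
hsa_circ_0024793	hsa-miR-193b-3p	1	≤10^−8
hsa_circ_0024793	hsa-miR-195-5p	2	≤10^−6
hsa_circ_0076213	hsa-miR-195-5p	1	≤10^−12
hsa_circ_0076214	hsa-miR-195-5p	2	≤10^−12
hsa_circ_0076215	hsa-miR-195-5p	2	≤10^−12
hsa_circ_0076216	hsa-miR-195-5p	1	≤10^−12
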