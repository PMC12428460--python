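circ_id	host_gene	chrom	start	end	spliced_length
hsa_circ_0024791	CHEK1	chr11	125625000	125627100	480
hsa_circ_0024793	CHEK1	chr11	125626200	125631900	910
hsa_circ_0024794	CHEK1	chr11	125628400	125630100	620
hsa_circ_0076213	PIM1	chr6	37138100	37140000	540
hsa_circ_0076214	PIM1	chr6	37138100	37141200	760
hsa_circ_0076215	PIM1	chr6	37138500	37142600	880
hsa_circ_0076216	PIM1	chr6	37139000	37143400	1050
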