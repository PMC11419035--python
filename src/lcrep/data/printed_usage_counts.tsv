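# Published per-cohort sequence counts used for share arithmetic.
# five_genes = sequences derived from IGKV1-33, IGLV1-44, IGLV2-14, IGLV3-1, IGLV6-57.
cohort	quantity	count	total
AL	five_genes	482	781
MM	five_genes	316	1122
OAS	five_genes	1424811	8047747
OAS	kappa	4278425	8047747
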