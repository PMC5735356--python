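mirna_id	tw_tpm	tpm_12h	log2fc_12h	pvalue_12h	fdr_12h	tpm_18h	log2fc_18h	pvalue_18h	fdr_18h
pxy-mir-7b-5p	17.64	3.92	-2.169925	3.29E-20	2.44E-19	2.6	-2.762267033	5.81E-27	5.52E-26
pxy-mir-2768-3p	14.23	4.35	-1.709848	1.94E-12	9.50E-12	5.1	-1.48036651	1.35E-10	6.30E-10
pxy-mir-79-3p	26.74	8.92	-1.583884	5.50E-20	3.82E-19	9.06	-1.56141651	4.42E-20	3.36E-19
pxy-mir-8507-3p	124.38	43.84	-1.504435	8.98E-81	1.61E-79	57.56	-1.111616025	2.44E-52	3.97E-51
pxy-mir-2a-3p	11.49	5.11	-1.168984	2.08E-06	6.78E-06	2.39	-2.265296275	1.16E-14	6.63E-14
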