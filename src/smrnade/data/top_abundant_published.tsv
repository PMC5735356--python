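mirna_id	mature_sequence	TW	12h	18h	24h	36h
pxy-mir-1-3p	TGGAATGTAAAGAAGTATGGAG	371221	289079	276684	241868	404656
pxy-let7-5p	TGAGGTAGTAGGTTGTATAG	77144	62823	67701	101438	64418
pxy-mir-184-3p	TGGACGGAGAACTGATAAGGGC	45689	37401	40854	48942	27575
pxy-mir-10-3p	CAAATTCGGTTCTAGAGAGGTTT	18052	11877	12032	13447	16493
pxy-mir-31-5p	AGGCAAGATGTCGGCATAGCTGA	12857	11904	13039	12037	10224
pxy-mir-2755-3p	CACCCTGTCAGACCATACTTGTT	11483	10586	10295	13527	8105
pxy-miR-281-5p	AAGAGAGCTATCCGTCGACAGT	9156	10361	10020	7132	10957
pxy-mir-10-5p	TACCCTGTAGATCCGAATTTGT	6647	4482	4503	6458	5884
pxy-mir-276-3p	TAGGAACTTCATACCGTGCTCT	4699	3004	2867	2217	6354
pxy-mir-279c-3p	TGACTAGATCCATACTCGTCTG	4658	5833	5468	7341	6376
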