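category	TW_count	TW_percent	h12_count	h12_percent	h18_count	h18_percent	h24_count	h24_percent	h36_count	h36_percent
high_quality_total	11861547	100	11872699	100	11944980	100	11956814	100	11866077	100
three_prime_adapter_null	27731	0.23	45757	0.39	3422	0.03	2394	0.02	29205	0.25
insert_null	8951	0.08	4048	0.03	6282	0.05	4351	0.04	10499	0.09
five_prime_contaminant	205353	1.73	61614	0.52	49186	0.41	25940	0.22	75571	0.64
shorter_than_18	595179	5.02	105692	0.89	65511	0.55	131053	1.1	522744	4.41
polyA	907	0.01	142	0	130	0	134	0	275	0
clean	11023426	92.93	11655446	98.17	11820449	98.96	11792942	98.63	11227783	94.62
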