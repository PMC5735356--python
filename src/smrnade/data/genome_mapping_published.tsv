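library	mapped_reads	clean_reads	percent
TW	6784087	11023426	61.54
12h	6965570	11655446	59.76
18h	7410628	11820449	62.69
24h	7023256	11792942	59.55
36h	6510880	11227783	57.99
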