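name	role	sequence	phosphorylated
Ubp4''a1	main	TTCGCGGTGGGCCTCGAGAATCTAGGAAATTCCTGCTATATGAACTGCATTATCC	true
Ubp4''a2	helper	CAGCTCATGCGTCCCTAAAATACACTGGATAATGCAGTTCATATAGCAGGAATTTCCTAG	false
Ubp4''a3	main	AGTGTATTTTAGGGACGCATGAGCTGACGCAGATCTTCCTTGACGATTCGTATGCGAA	true
Ubp4''a4	helper	CCCTAGTTTAGAATTGATATTGATGTGCTTCGCATACGAATCGTCAAGGAAGA	false
Ubp4''a5	main	GCACATCAATATCAATTCTAAACTAGGGTCGAAAGGTATTTTAGCTAAATATTTCGCTCGTCTTGTAC	true
Ubp4''a6	helper	TTGGAGCCATCTACCTGTTCCTTATACATCATATGTACAAGACGAGCGAAATATTTAGCT	false
Ubp4''a7	main	ATATGATGTATAAGGAACAGGTAGATGGCTCCAAAAAAATTTCGATTAGCCCAATCAAATTTAAGCT	true
Ubp4''a8	helper	AACAGTGAGTTGACGGAACCACAGGCGAGCTTAAATTTGATTGGGCTAATCG	false
Ubp4''a9	main	CGCCTGTGGTTCCGTCAACTCACTGTTTAAAACAGCTTCACAGCAAGATTGTCAGGAATTTTGCC	true
Ubp4''a10	helper	GATCTTCATGCAAACCGTCAAGCAAGAATTGGCAAAATTCCTGACAATCTTGCTGTGA	false
Ubp4''a11	main	AATTCTTGCTTGACGGTTTGCATGAAGATCTGAACCAGTGCGGTTCTAACCCC	true
Ubp4''a12	helper	CCTCTTGGCTCAGTTCTTTCAACGGGGGGTTAGAACCGCACTGGTTCA	false
Ubp4''a13	main	CCGTTGAAAGAACTGAGCCAAGAGGCAGAAGCGAGGCGGGAAAAGCTGAGCCTC	true
Ubp4''a14	helper	GTTCCCATTCAATACTACTGGCTATGCGGAGGCTCAGCTTTTCCCGCCTCGC	false
Ubp4''a15	main	CGCATAGCCAGTAGTATTGAATGGGAACGCTTTCTGACCACGGATTTTAGCGTCATTGTG	true
Ubp4''a16	helper	AGCGAGAGGCATATTGCCCTTGAAAGAGGTCCACAATGACGCTAAAATCCGTGG	false
Ubp4''a17	main	GACCTCTTTCAAGGGCAATATGCCTCTCGCTTAAAATGCAAAGTATGCAGCCACACTTCA	true
Ubp4''aFor	primer	GGGGGAATTCGATATGTTCGCGGTGGGCCTCGAGAATC	false
Ubp4''bRev	primer	GGGGGGATCCTTATGAAGTGTGGCTGCATACTTTGCATTTTAAG	false
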