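name	role	sequence	phosphorylated
Ubp4'1	main	ATGTGCTACATGAATTGTATAATACAGTGTATCCTAGGAA	true
Ubp4'2	helper	AATCTGGGTCAGCTCATGCGTTCCTAGGATACACTGTATT	false
Ubp4'3	main	CGCATGAGCTGACCCAGATTTTTCTCGATGACTCCTACGCTA	true
Ubp4'4	helper	TAGAGTTAATATTGATGTGCTTAGCGTAGGAGTCATCGAGA	false
Ubp4'5	main	AGCACATCAATATTAACTCTAAACTAGGCTCTAAGGGCATCTTGG	true
Ubp4'6	helper	GCACGAGTCGAGCGAAATACTTTGCCAAGATGCCCTTAGAGCCT	false
Ubp4'7	main	CAAAGTATTTCGCTCGACTCGTGCACATGATGTATAAAGAGCAAGTA	true
Ubp4'8	helper	GGGGAAATGGATATTTTCTTAGAACCGTCTACTTGCTCTTTATACATCAT	false
Ubp4'9	main	GACGGTTCTAAGAAAATATCCATTTCCCCAATAAAATTTAAATTAGCATGTGGATCCGT	true
Ubp4'10	helper	GCGGTTTTGAACAACGAGTTTACGGATCCACATGCTAATTTAA	false
Ubp4'11	main	AAACTCGTTGTTCAAAACCGCCTCACAACAGGATTGTCAGTAA	true
Ubp4'For	primer	GGGGGAATTCGATATGTGCTACATGAATTGTATAATAC	false
Ubp4'Rev	primer	GGGGGGATCCTTACTGACAATCCTGTTGTGAG	false
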