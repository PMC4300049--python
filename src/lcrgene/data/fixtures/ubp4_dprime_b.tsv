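name	role	sequence	phosphorylated
Ubp4''b1	main	ACCACATATCAGCCCTTTACGGTACTGTCTATCCCTATACCCAAAAAGAATA	true
Ubp4''b2	helper	AGCAATCCTCGATAGTAATGTTATTGCGACTATTCTTTTTGGGTATAGGGATAGACAGT	false
Ubp4''b3	main	GTCGCAATAACATTACTATCGAGGATTGCTTCCGCGAATTCACCAAATGCGAAAATCTCGAGGTAG	true
Ubp4''b4	helper	TTCACAGTGCGGACAGAGCCATTGCTCATCTACCTCGAGATTTTCGCATTTGGT	false
Ubp4''b5	main	ATGAGCAATGGCTCTGTCCGCACTGTGAAAAACGTCAACCGTCAACTAAACAGCTGACCATTACC	true
Ubp4''b6	helper	TTTTAGATGGACAATGAGGTTCCGCGGCAAGCGGGTAATGGTCAGCTGTTTAGTTGACGGT	false
Ubp4''b7	main	CGCTTGCCGCGGAACCTCATTGTCCATCTAAAACGTTTTGATAACCTGCTTAACAAAAACA	true
Ubp4''b8	helper	AGCAGAAATGGATAAATCACGAAGTCATTGTTTTTGTTAAGCAGGTTATCA	false
Ubp4''b9	main	ATGACTTCGTGATTTATCCATTTCTGCTGGATTTAACGCCTTTTTGGGCAAACGACTT	true
Ubp4''b10	helper	TTCACCCCCGGCGGGAACACGCCATCAAAGTCGTTTGCCCAAAAAGGCGTTA	false
Ubp4''b11	main	TGATGGCGTGTTCCCGCCGGGGGTGAACGACGATGAATTACCAATCCGAGGTCAGATCCCGCC	true
Ubp4''b12	helper	CACGCGACACCATACAATTCATATTTAAATGGCGGGATCTGACCTCGGATTGGTAATT	false
Ubp4''b13	main	ATTTAAATATGAATTGTATGGTGTCGCGTGCCATTTCGGGACACTGTATGGCGGCCAC	true
Ubp4''b14	helper	TTAAACCTTTTTTCACATAAGCCGTATAGTGGCCGCCATACAGTGTCCC	false
Ubp4''b15	main	TATACGGCTTATGTGAAAAAAGGTTTAAAAAAGGGATGGCTTTATTTTGATGA	true
Ubp4''b16	helper	GCGTCGGCTTTGTTTTTAACCGGCTTATACTTGGTATCATCAAAATAAAGCCATCC	false
Ubp4''b17	main	TACCAAGTATAAGCCGGTTAAAAACAAAGCCGACGCAATTAATAGCAATGCATATGTTCTGTTCTAT	true
Ubp4''bFor	primer	GGGGGGATCCACCACATATCAGCCCTTTACGGTAC	false
Ubp4''bRev	primer	GGGGTCTAGATTAATGGTGATGGTGATGGTGATAGAACAGAACATATGCATTGCTATTAATTGCG	false
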