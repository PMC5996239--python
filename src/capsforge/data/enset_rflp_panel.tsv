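no	forward_primer	reverse_primer	product_size_bp	enzyme	accession	start	end
1	TAGACTGCCAAGAGACTGCC	GAGTTTGTTCTCCACTTGCTG	395	EcoRV	JTFG02000023	86778	87172
2	CAATGAAATGAGCTCTCGAATGA	CCTCCCTCCCTCTACACAAG	453	ClaI	JTFG02000451	2383	2835
3	AGCTGCCTACTTATGTGCCA	AGGATGGGAGGATTTCACTCA	296	ClaI	JTFG02001079	44094	44389
4	GAAAGATTCAACCACGCAACA	CAAAGTTGCCCAAATAATAGGGG	100	HindIII	JTFG02001701	16598	16697
5	ACGTAGGAAACAGAAGGCGT	AGAATGAAAACCGGACAGATGA	400	BglII	JTFG02004430	21696	22095
6	GACCAAGGTTGCAACGATGT	AACTCCCTAAAGTGGACCCG	296	HindIII	JTFG02004708	2865	3160
7	TGCCAATTGTAGCACGCTTT	TCCCAATGATCAGGATGTCATC	321	BglII	JTFG02007725	4758	5078
8	AGCTGATCGGTAGGCTGTTT	TGTTCACTTGCTCAACTTCAATG	329	EcoRV	JTFG02008123	5568	5896
9	CGAAGGAACAAGAGGACGT	CGGCATGAACTAACCGCTTA	380	BglII	JTFG02010045	2436	2815
10	AGAGTAGAGGTCAGCGCATC	AGGCGAGTGACTAAAGTGCT	385	HindIII	JTFG02015245	4512	4896
11	GTCATGTAGAATTCAAAAGCCCA	ACCCATGACCAAGACTTTTCT	458	ClaI	JTFG02000797	35394	35851
12	GCAGAATCCCGTGAACCATC	TGTAAGTTTCTTCTCCTCCGCT	377	BglII	JTFG02001387	44650	45026
13	TGCTTTAACCTAGTGAGCTACAA	ACGTCGCCCTTTTACTTTTCT	400	BamHI	JTFG02001793	29736	30135
14	GCCCATGCCATTCTTAAGGA	TCCAATTCCATCCTTCTTCATCT	398	BglII	JTFG02003127	17456	17853
15	ACTACACAATCCTGGTCCAAAA	CGTAGTTTCCGCCCTTTGAG	113	EcoRV	JTFG02004277	15220	15332
16	CCTGGTTGAGAATGCGGATG	CGACCAATTACACTAAGCCCA	419	BglII	JTFG02006088	4069	4489
17	TCCAGCCCAACAATTGATTCTT	CTGAACCTCGGCCAACCT	400	ClaI	JTFG02006206	13985	14384
18	TGCCAACCGAACCTCTCAG	TCAGCCATCTACGACATTTACA	400	PstI	JTFG02010369	10275	10674
19	TGCTTACTGACTATGGAGAGCT	TGCCTGTTTGAGTCCATATAAGT	487	BamHI	JTFG02011833	6273	6759
20	CTCGTTAAGGTTCCCCATGC	CCAGCGTGGGAGATCTTTTG	452	EcoRV	JTFG02024842	425	876
21	CGAGGGCTTCATCGAAAAGG	GCTGCCGACGAGTTGTTC	391	BamHI	JTFG02043259	629	1019
22	CGATCGTTACGTTGCTTCAG	GGAGCCACAACCAACCAATT	446	PstI	JTFG02009519	11979	12424
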