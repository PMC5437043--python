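no	locus	region	location	motif	min_units	max_units	primer_f	primer_r	product_bp	tm_c
1	trnT-trnL	LSC	spacer	AT	6	6	AGAAATTCAATTCCATATTCA	CATTGATGTATCCGCAATAT	232	51
2	trnT-trnL	LSC	spacer	AT	6	6	CTAAATAGAAATTCAATTCCT	CCTTTACCCCTCCTTCCTAA	185	53
3	trnL intron	LSC	intron	T	8	14	TGGATTGAGCCTTGGTATA	TCCTTTCTGTCATTTCGATT	231	50
4	trnE-trnT	LSC	spacer	A	8	10	AATATGAATCTTACCCACTTCC	TGAACCGATGACTTACGCAA	180	52
5	trnR-atpA	LSC	spacer	A	9	9	TTGGACGCATTTATTTCTAC	CGAAGAAGCTGAAACCCTT	250	52
6	rps16-trnQ	LSC	spacer	A	8	13	AAAGTCTCGTGTAAGGTAT	ATGTTGGATACACTGAATA	225	53
7	rps16 intron	LSC	intron	T	8	11	CTCTTTCTATCATCCTTCCAT	CCCACTATAAACTTAGTAACTAT	225	51
8	petN-psbM	LSC	spacer	A	8	10	TTCACTTGTAGTATGGGGAAG	GAGGATTAAATAGAAGAATCT	232	50
9	trnL-trnF	LSC	spacer	T	8	15	TTCCTCGCTCTTTATTTATCC	CAATAACGGAGATTCCTTGAA	209	54
10	rps8-rpl14	LSC	spacer	T	8	11	TAGTTATTGGTGTCTCCTCAT	TATCTGAAATAGATCCGATTA	160	51
11	psbK-psbI	LSC	spacer	A	8	10	AAGGAAATCTCGATTCAATTC	AAAGGAAAGGTCAGAACAAAA	241	53
12	psbK-psbI	LSC	spacer	A	8	10	CTTTAATCAGCTAATCAACTT	CTATTTGATATGAAGCTCTAA	225	50
13	psbK-psbI	LSC	spacer	A	8	10	AGATATGGATATGGCAAGAAA	TACAAATCTCCAAGATAAGAT	217	52
14	ccsA-ndhD	SSC	spacer	T	8	11	AAATCGTCTGATACGCAATGC	TTGACTTTCATATTTTCACGA	174	56
15	rps16 intron	LSC	intron	T	8	11	AACTCAAGTTGGGTAGTTTTG	TAAGGATCACCGAAGTAATGT	224	51
16	psbA-trnK	LSC	spacer	T	8	14	CTATGCCAATGTCAACCAATC	CTTTCTTTAATCTTCCTCCAA	246	55
17	matK-5′trnK	LSC	spacer	A	8	10	AATCACTCTTTTGACTTTGGAA	AATTTGAATGATTACCCGTAC	214	54
18	matK-5′trnK	LSC	intron	A	8	10	CTTACTCGAATTGGAGCCATA	CCGCGACTGATCCTGAAAGGT	216	55
19	atpB-rbcL	LSC	spacer	T	8	14	ATAGCAAGTTGATCGGTTAAT	CTAGATGTGAAAAGAGGCATA	224	51
20	atpB-rbcL	LSC	spacer	T	8	14	TTCTATCTTTATCTTTACTTTCG	GAGTATGAAGAATAATGAATATGA	262	50
21	atpB-rbcL	LSC	spacer	T	8	14	CTATCTTTATCTTTACTTTCG	GAAGAATAATGAATATGATAGA	255	50
22	trnC-petN	LSC	spacer	A	8	12	ATCCTGTTGATCGAACTTGAC	CAATTCAGAATAGCCCAAACC	216	54
23	trnC-petN	LSC	spacer	A	8	12	ACTGATTTGTATCCAGACTCA	TCTTACTTACGGCTCTTTATG	218	50
24	trnC-petN	LSC	spacer	A	8	12	ACTAGAGGCTCTGAGTGCTGC	TCATAGTGGAATGAATGGTGC	235	55
25	rps18-rpl20	LSC	spacer	A	8	8	AAACTCCAATAGGAAATCAAG	ACAAGAATGATTGAAACAGGA	213	52
26	petA-psbJ	LSC	spacer	T	8	14	AATAAAGTTGGTAAAAGTGCC	TCCTTTGTATTTGTATGCTTC	189	51
27	ycf4-cemA	LSC	spacer	T	8	14	AGGAAGAAAAGAAGAGGAAATC	CCTATAACTCTAACAAGAACAA	217	54
28	rps2-rpoC2	LSC	spacer	T	9	13	CCATTTATTAGTACCATGACCA	CTAATACCTAAAGCATTAGTTA	207	55
29	trnF-trnV	LSC	spacer	A	8	9	ATTGAGACGGATCGGGATAGA	GCAAAATGATAAGAATCGGAG	229	56
30	atpI-rps2	LSC	spacer	A	8	10	ATTATTTTGATTCAACCATCTC	GATTGTTACTCTTTTGGTTTG	189	51
31	psbZ-trnG	LSC	spacer	A	8	10	CCGATCCAAATAATCCTTCTA	TTTTCTTCGTTCCTGATACGT	264	54
32	psaA-ycf3	LSC	spacer	A	8	11	ATGAGATACCGTAGAAAATGT	CTGCTGAGTATTGGAAACAAG	240	51
33	psbE-petL	LSC	spacer	T	8	13	GCTCCACAAATTCTTGTATGT	AATTTCCTTTCGGTAATGATC	203	53
34	psbE-petL	LSC	spacer	T	8	13	ATTAGTGGCTTCATCATAGTAAT	CAAAGTGAAATAGTGTATTAGCAT	244	50
35	psbE-petL	LSC	spacer	T	8	13	ACTTTGAAATTAGAAACTGAAGCTA	ACAACAGTTGCATCACGAATA	232	54
36	psbE-petL	LSC	spacer	T	8	13	TTCTTTTGAATCGAGTTGGTCC	TTTCAATCCAGATACGACGGT	207	56
37	trnF-ndhJ	LSC	spacer	A	8	9	TTCATTGAGACGGATCGGGATA	CAAAATGATAAGAATCGGAGTT	231	55
38	trnD-trnY	LSC	spacer	T	8	10	TTTCAGAAGAGCATTCTATTT	CTCCATGAAGAAGATCTAAAG	249	50
39	trnS-psbZ	LSC	spacer	A	8	10	GCTATCAACCACTCAGCCATC	TCCTCCAAACTACCAACAAAT	247	55
40	rpoC1 intron	LSC	intron	T	8	15	CTACTCTTTACTCAAGTTCCCAA	AAATCCTTTACGAGTCCCACA	202	55
41	petB intron	LSC	intron	A	8	11	AACCTTTGAGTTTAGCTTTGG	TACAATCTCAAGTTGGCTCAT	185	53
42	clpP intron2	LSC	intron	A	8	11	GTTTGTGACGCTGAAATTGAC	TACTATGCCTTCGCTGTATCG	200	55
43	clpP intron2	LSC	intron	A	8	11	TCAAATTGGGAATAACTCTTC	AATTACCAAACGTCTAGCATT	228	51
44	ycf3 intron1	LSC	intron	A	8	11	ATAGATGTAACCTTTTGCTCA	AGGCATTTACCTATTACAGAG	241	50
45	3′rps12-trnV	IR	spacer	T	9	16	CTTTGCCCCTCATTCTTCGAG	ATGGGTCAGATTCTACAGGATCAAC	236	56
46	3′rps12-trnV	IR	spacer	T	9	16	AGTAGTTAATGGTGGGGTTAC	GCTCTATTCGAGACTGGTAGG	248	52
47	trnI intron	IR	intron	G	8	10	TTCTCCTCAGGAGGATAGATG	TCTGTGAAGATGCTGTGTTAG	223	53
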