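# 17-plex horse tetra/penta-STR panel + amelogenin sex marker.
# One row per marker. Dyes normalized (6-FAM -> FAM). ref_size for amel is "Y;X" (two products).
# position_mb is the approximate chromosomal location encoded in the marker name.
# stutter_pct/mut_rate: ND/NA where not determined/applicable.
name	chromosome	position_mb	dye	unit	structure	sws	conc_uM	ref_size	range_min	range_max	wt_avg	n_alleles	stutter_pct	mut_rate	primer_f	primer_f_label	primer_r
amel	XY		HEX	GA	[GA]12	NA	0.7	113;134	113	150	134	11	ND	NA	CCAGGATGAGGTGGTAGCTTTTATA	HEX	gtATGTGAACAATTGCATATTGACTTAATCT
ECA28.003.6	28	3.6	HEX	AGAT	[AGAT]13	468	0.3	179	159	187	171	8	10.3	0.18	aGGTAGCATAACCCCTACTGAGATAA	HEX	gtttcttGGGTTCCACATGTCAAAACAAA
ECA15.001.6	15	1.6	HEX	TCTA	[TCTA]4[TCTG][TCTA]11	602	1.3	245	228	257	242	8	9.1	0.33	TGCTTGGTGTACAGGCCTCAG	HEX	gtttcttTTTCTGAGAGAAAGCTGAAAGTATG
ECA07.065.4	7	65.4	HEX	ATAG	[ATAG]13	477	1.0	291	267	305	283	8	7.9	0.19	aGAACAATGAGCAGGGAGTACAA	HEX	gAGCAAGACTTGAAGAGGAATGGA
ECA05.065.8	5	65.8	HEX	GTTTT	[GTTTT]11	504	1.5	347	312	361	336	8	1.7	0.22	GGACTTTCAAAACTCACCCAAA	HEX	GATACAAAGTCCATGATCAAAACAAA
ECA12.004.8	12	4.8	HEX	ATCT	[ATCT]ATC[ATCT]2[ATCC][ATCT][ATTG]TCT[ATCT]9ATC[ATCT]3[ATCC]2[ATCT]	633	5.0	431	410	435	420	9	3.2	0.37	AAGGAGCAAGTTCAGGCAAA	HEX	gtttcttTCATCCCTTGTACGCCTCTAA
ECA24.028.9	24	28.9	NED	TCTCT	[TCTCT]11	495	1.0	120	80	137	113	9	6.2	0.21	TTTCAGGTTCTCGTTACTCAGATAGAA	NED	ATATTCTTGTAGGTAGGGTTT
ECA22.012.1	22	12.1	NED	AGAT	[AGAT]12	510	0.5	169	142	172	160	7	2.5	0.23	CTCATGGTCTTTTAATTTTGAGTTATAC	NED	gtttcttGCAACACATGTAACTGACCCAAA
ECA21.027.5	21	27.5	NED	GATA	[GATA]2[GTTA][GATA][GACA][GATA]2GAT[GATA]11[GATC]	608	1.5	221	193	236	215	6	7.3	0.34	TCCAAGGACCTTCTTCCAAA	NED	gtttcttAAATTAGTGAATTTGGAGAAAACAA
ECA25.011.9	25	11.9	NED	ATCT	[ATCT]3[ATCC][ATCT]11[ATCC]4	602	1.0	248	235	267	250	8	10.7	0.33	TCTGAGAGGTGATGGCAAAA	NED	gtttcttTTCATTGTGTACAGTGTGGTATCAA
ECA27.020.1	27	20.1	NED	AGAT	[AGAT]12	582	2.5	307	285	326	306	7	7.3	0.31	TTGAATTGCCATGATTAGGAA	NED	gTGAATTTGGGCTGAGATTGAA
ECA14.076.8	14	76.8	NED	CATC	[CATC]2[TATC][CATT][TATC][CATC]4[CAAC][CATC][CAAC][CATC]10	663	1.5	354	346	362	356	4	8.0	0.42	CCTACTTAGTCCCCCTTCCTGAAA	NED	gtttcttCAGGACAGAGGTTAAGTCACAAATAA
ECA04.104.2	4	104.2	NED	CTAT	[CTAT]GTG[CTAT]9CAT[CTAT][CTGT][CTAA]T[CTAT]CAT[CTAT]4[CTAG]T[CTAT]CAT[CTAT]2	931	2.5	428	411	436	422	7	6.6	0.92	AGGAGTGGCAGTTGGTTGTGG	NED	gtttcttCACCCATCAATGCACAAATCTGCAGAAAA
ECA04.035.5	4	35.5	FAM	TAAAA	[TAAAA]9	405	0.4	127	97	131	114	7	1.2	0.13	CCCACATGACAAAAGCACAA	FAM	gTTCTCTCTGAGTCCAGATGCAA
ECA02.105.5	2	105.5	FAM	AGAA	[AGAA]CT[AGAA]14[AGGA]A[AGAA]2[GGAA]2[AGAT]2	647	1.0	198	172	207	191	12	6.6	0.39	AGCTCTTGAGCCCTCTTTGTAA	FAM	gtttcttTTCCTTCATGCTGTTCCTGTAA
ECA03.025.9	3	25.9	FAM	AGAT	[AGAT]5GAT[AGGT][AGAT]10	542	1.0	254	238	261	252	7	7.5	0.26	AGTAACATTTGGGTCATCTGAAA	FAM	gCGCAGCTCCTCATACTGAAA
ECA01.102.4	1	102.4	FAM	ATCT	[ATCT]7ATC[ATCT]12	671	1.0	296	261	307	297	9	9.8	0.43	TTTGGAGATGTTGGAAGTTAAGG	FAM	gtttcttAAGGGGAGAGGATGGAGCAAGAAAGAA
ECA20.003.8	20	3.8	FAM	TATC	[TATC]18[TGTC]	672	4.8	409	354	417	381	17	11.2	0.43	AAATAAGATGAATAGACAGGCCCTAA	FAM	gtttcttTCCGACTCATCCTACAGCAA
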