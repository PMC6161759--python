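no	intron_id	size_bp	sequencing_result	existence	splice_variants	homolog_count
1	AT1G62580.1-5	27	cDNA	No	3	2
2	AT2G04395.1-2	29	cDNA	No	5	1
3	AT5G51795.1-2	28	gDNA	UJ	1	2
4	AT2G07240.1-4	30	gDNA	UJ	1	0
5	AT2G21330.3-6	30	cDNA	No	3	2
6	AT2G44980.1-10	30	cDNA	No	3	0
7	AT5G50080.1-1	27	cDNA	No	2	3
8	AT3G53740.1-3	27	cDNA	No	4	2
9	AT2G41700.2-18	30	cDNA	No	2	0
10	AT2G31370.5-6	28	cDNA	No	7	1
11	AT1G51490.1-10	23	cDNA	No	1	0
12	AT3G51260.2-3	21	cDNA	No	2	1
13	AT3G55280.3-3	18	cDNA	No	3	1
14	AT4G35300.3-3	30	cDNA	No	11	0
15	AT1G01620.2-1	29	cDNA	No	2	11
16	AT3G53980.2-2	25	cDNA	No	2	1
17	AT3G59350.3-6	23	cDNA	No	6	8
18	AT2G05520.2-2	21	cDNA	No	6	5
19	AT2G10930.1-1	29	gDNA	UJ	1	1
20	AT4G38300.1-2	28	cDNA	No	1	1
21	AT1G71280.1-2	25	cDNA	No	2	2
22	AT3G28170.1-1	10	gDNA	UJ	1	0
23	AT1G18050.1-3	8	cDNA	No	1	0
24	AT5G22050.1-7	20	gDNA	UJ	2	0
25	AT2G40920.2-1	16	cDNA	No	2	2
26	AT1G27290.2-2	16	cDNA	No	2	0
27	AT1G02950.3-4	15	cDNA	No	5	0
28	AT1G31170.3-5	15	cDNA	No	5	0
29	AT5G48760.2-1	13	cDNA	No	2	3
30	AT2G14720.2-1	10	cDNA	No	2	1
31	AT5G30341.1-1	30	cDNA	No	1	1
32	AT4G06479.1-1	29	gDNA	UJ	1	0
33	AT2G13125.1-1	29	gDNA	UJ	1	3
34	AT2G06500.1-1	29	gDNA	UJ	1	0
35	AT1G49015.1-2	29	gDNA	UJ	1	2
36	AT3G28020.1-4	28	gDNA	UJ	1	1
37	AT1G76720.1-13	26	gDNA	UJ	2	4
38	AT2G18530.1-2	24	gDNA	UJ	1	2
39	AT2G24340.1-3	24	gDNA	UJ	1	0
40	AT3G27600.1-1	23	gDNA	UJ	1	0
41	AT2G13125.1-2	23	gDNA	UJ	1	0
42	AT2G11010.1-4	23	gDNA	UJ	1	3
43	AT1G35860.1-1	23	gDNA	UJ	1	0
44	AT2G05440.4-2	21	cDNA	No	9	3
45	AT3G05450.1-1	19	cDNA	No	1	0
46	AT1G72270.1-13	18	cDNA	No	1	1
47	AT4G13850.2-5	15	cDNA	No	4	1
48	AT1G24460.1-4	14	cDNA	No	2	0
S1	AT1G76530.1-5	31	cDNA	80 bp	3	2
S2	AT4G01780.1-2	32	gDNA	UJ	1	0
S3	AT4G28670.1-3	34	cDNA	74 bp	1	0
S4	AT4G20900.1-4	35	cDNA	83 bp	2	1
S5	AT5G07510.2-2	36	cDNA	No	3	3
S6	AT2G36010.2-1	36	cDNA	516 bp	3	0
S7	AT3G56300.1-5	37	cDNA	No	3	1
S8	AT1G02670.1-5	37	cDNA	No	7	1
S9	AT1G16150.1-2	38	cDNA	92 bp	1	1
S10	AT1G14390.1-4	39	cDNA	96 bp	1	4
S11	AT3G13920.2-5	41	cDNA	No	5	2
S12	AT4G04710.1-3	43	cDNA	82 bp	4	5
S13	AT5G40600.1-1	44	cDNA	534 bp	4	0
S14	AT1G19090.1-3	44	cDNA	No	1	1
S15	AT4G04680.1-4	45	cDNA	No	2	1
S16	AT1G48740.1-4	45	cDNA	81 bp	4	3
S17	AT3G11040.1-9	45	cDNA	111 bp	2	2
S18	AT2G35075.1-2	46	gDNA	UJ	1	0
S19	AT4G15300.1-3	46	cDNA	88 bp	3	3
S20	AT4G14310.2-2	47	cDNA	363 bp	2	0
S21	AT3G43290.1-1	51	gDNA	UJ	1	2
S22	AT3G56160.1-1	52	cDNA	133 bp	5	0
S23	AT3G09090.2-12	55	cDNA	71 bp	3	0
S24	AT1G15120.2-5	55	cDNA	92 bp	2	1
S25	AT4G12750.1-7	56	cDNA	98 bp	1	0
S26	AT4G21820.1-9	56	cDNA	102 bp	3	0
S27	AT4G24930.1-3	59	cDNA	Yes	1	0
S28	AT3G23080.2-4	59	cDNA	Yes	3	2
S29	AT2G30650.1-3	59	gDNA	UJ	2	0
S30	AT2G29390.1-5	59	cDNA	95 bp	6	1
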