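source_table	position	gene	hgvs_c	var_type	distance	spliceai	spcards	outcome	alteration	fraction_count	protein_length	fraction_pct	golden	note
T1	2:48956335:T:A	LHCGR	c.265A>T	Mis	32	0.5452	9	Exon 3 skipping	p.E79_I103del	25	699	3.58	1
T1	5:56155534:T:A	MAP3K1	c.634-8T>A	Intron	-8	0.8771	13	Intron 2 6bp retention	p.A211_A212insLA	2	1512	0.13	1
T1	9:99017150:C:T	HSD17B3	c.277G>A	Mis	-1	0.5969	14	Exon 3 skipping	p.L68Sfs*6	242	310	78.06	1
T1	X:66905839:T:G	AR	c.1769-13T>G	Intron	-13	0.9299	8	Intron 2 69bp retention	p.E589_E590insEIPEERDSGNSLSGLSTLVFVLP	23	920	2.5	0	insertion not 3'-normalized in source
T1	X:66931411:G:A	AR	c.2053G>A	Mis	-121	0.7255	5	Exon 4 123bp deletion	p.A629D*	292	920	31.74	0	ambiguous alteration notation
T1	1:76262914:G:A	MSH4	c.244G>A	Mis	-1	0.8785	5	Exon 1 skipping	NA	NA	NA	NA	0	start-exon skipping; no protein prediction in source
T1	1:109198245:C:T	HENMT1	c.226G>A	Mis	-38	0.5469	6	Exon 4 skipping	p.V51Gfs*36	342	393	87.02	1
T1	3:52418934:G:A	DNAH1	c.8455G>A	Mis	-60	0.7429	4	Exon 53 skipping	p.I2775_K2838del	63	4265	1.50	1	printed count 63; inclusive span 2775-2838 is 64 residues and matches the printed 1.50%
T1	3:180334459:G:A	CCDC39	c.2431C>T	Mis	25	0.6198	4	Exon 18 skipping	p.C803_Q862del	60	941	6.38	1
T1	4:57686748:G:C	SPINK2	c.206-3C>G	Intron	-3	0.9482	14	Intron 2 2bp retention	p.A69Sfs*12	65	134	48.51	1
T1	7:117175465:G:C	CFTR	c.743G>C	Mis	-1	0.9534	14	Exon 6 skipping	p.G194Rfs*7	1270	1464	86.75	1
T1	7:117180399:A:G	CFTR	c.1115A>G	Mis	-2	0.5325	11	Exon 8 skipping	p.T291Ifs*13	1189	1480	80.34	1
T1	7:127239489:G:A	FSCN3	c.1175G>A	Mis	55	0.6137	6	Exon 5 68bp deletion	p.G374_R392del	18	497	3.62	0	68 bp deletion is frame-shifting yet an in-frame deletion is printed; span count off by one
T1	9:127255309:C:T	NR5A1	c.990G>A	Syn	-1	0.8657	15	Exon 5 skipping	p.V291_E330del	40	461	8.68	1
T1	14:60923816:G:C	C14orf39	c.1180-3C>G	Intron	-3	0.3554	14	Exon 15 skipping	p.A394*	193	587	32.88	1
T1	15:45258441:G:A	TERB2	c.434G>A	Mis	-1	0.9783	11	Exon 5 skipping	p.H117Pfs*23	103	220	46.82	1
T1	16:1912054:T:A	MEIOB	c.191A>T	Mis	64	0.6563	2	Exon 4 69bp deletion	p.N43_A66delinsT	24	471	5.10	1
T1	18:13087149:A:G	CEP192	c.5750A>G	Mis	-128	0.9773	6	Exon 31 133bp deletion	p.I1873Hfs*7	664	2537	26.17	1
T1	X:69871300:C:T	TEX11	c.1483G>A	Mis	-1	0.8886	12	Exon 17 skipping	p.V430_K475del	46	940	4.89	1
T1	2:84932870:A:G	DNAH6	c.8726A>G	Mis	-2	0.285	12	Exon 52 skipping	p.K2922_R2906delinsN	85	4158	2.04	0	reversed residue range in source
T1	3:52428478:C:G	DNAH1	c.10627-3C>G	Intron	-3	0.6792	17	Exon 67 skipping	p.S3543Gfs*44	722	4265	16.93	1
T1	10:105944769:C:T	CFAP43	c.2141+5G>A	Intron	5	0.7465	15	Intron 16 16bp retention	p.R715Yfs*12	950	1665	57.06	1
T1	10:118615261:A:G	ENO4	c.293A>G	Mis	-2	0.7707	13	Exon 2 skipping	p.A58_K98del	41	625	6.4	0	41/625 is 6.56%, printed 6.4%
T1	11:113230183:G:A	TTC12	c.1470G>A	Syn	-1	0.9248	15	Exon 16 skipping	p.V491_T513del	23	680	3.23	0	23/680 is 3.38%, printed 3.23%
T1	12:63962999:C:T	DPY19L2	c.2126+5G>A	Intron	5	0.3764	15	Exon 20 skipping	p.D634Gfs*4	124	758	16.89	0	124/758 is 16.36%, printed 16.89%
T1	12:124416551:G:A	DNAH10	c.12838G>A	Mis	64	0.8015	5	Intron 74 retention and exon 75 65bp deletion	p.A3744Vfs*30	212	3956	5.36	1
T1	16:70884561:G:C	HYDIN	c.12441-3C>G	Intron	-3	NA	15	Exon 74 31bp deletion	p.R4148Sfs*4	973	5121	19.00	1
T1	17:11660970:A:G	DNAH9	c.6956A>G	Mis	-40	0.7695	2	Exon 35 38bp deletion	p.G2283Afs*1	2202	4486	49.11	0	fs*1 is not representable; printed count off by one
T3	17:2573457:G:T	PAFAH1B1	c.400G>T	Mis	1	NA	10	Exon 6 skipping	p.V134Afs*7	276	410	67.32	1
T3	18:23845279:G:A	TAF4B	c.489G>A	Syn	-1	0.3492	12	Exon 2 skipping	p.V117Lfs*3	750	867	86.51	1
T3	X:77388835:C:G	TAF9B	c.592G>C	Mis	1	0.9007	13	Exon 6 skipping	p.A161_P197del	37	251	14.74	1
T3	6:32006858:C:G	CYP21A2	c.293-13C>G	Intron	-13	0.7509	6	Intron 2 19bp;26bp;33bp retention	p.Y98Sfs*10;p.Y98Sfs*53;p.Y98F2938insPTLQPPPPPAD	387;344;12	495	78.18;69.49;2.42	0	multi-product entry; counts inconsistent with the counting conventions; third product string garbled in source
T3	3:69075143:T:C	TMF1	c.2859+4A>G	Intron	4	0.3903	14	Exon 14 skipping	p.l920_G953del	33	1091	3.02	0	inclusive span 920-953 is 34 residues (3.12%); source printed 33 (3.02%)
T3	1:225418858:G:A	DNAH14	c.6452+5G>A	Intron	5	0.829	14	Exon 42 skipping	p.S2147Rfs*13	2470	4617	53.49	0	2470/4617 rounds half-up to 53.50; source printed truncated 53.49
T3	3:52394439:A:G	DNAH1	c.4684A>G	Mis	-2	NA	9	Exon 28 skipping	p.Y1525_R1562del	37	4265	0.87	0	inclusive span 1525-1562 is 38 residues (0.89%)
T3	3:52420361:G:A	DNAH1	c.8811G>A	Syn	-1	0.4561	11	Intron 55 retention	p.E2937_V2938insVGSRASPGIPSHMPLSSSLPSAHPLGPSSLPHPPHSSPQGPSRSMGTWVGEQKELWAEANLGGSLDMPVSCGSRDLVGRANLSGRVPAEGCPLVLSLPHLVAGPA	105	4265	2.461	0	three-decimal percentage in source
T3	10:105990345:T:G	CFAP43	c.319+3A>C	Intron	3	0.7793	14	Exon 5 skipping	p.R195Sfs*31	1470	1665	88.29	1
T3	12:124364181:G:A	DNAH10	c.8113G>A	Mis	1	0.1213	10	Exon 49 skipping	p.V2705_Q2760del	56	4471	1.25	1
T3	12:124272548:A:G	DNAH10	c.1436A>G	Mis	-2	0.7124	12	Intron 10 79bp retention	p.V480Ifs*17	3991	4471	89.26	1
T3	17:7722099:G:A	DNAH2	c.10670+5G>A	Intron	5	0.9686	13	Exon 69 skipping	p.G3464Pfs*14	963	4427	21.75	1
T3	19:2097331:G:C	IZUMO4	c.298G>C	Mis	-1	0.8731	14	Intron 2 retention	p.K101Yfs*74	113	214	52.80	1
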