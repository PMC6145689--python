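row	uniprot	gene	protein	hexnac	hex	fuc	neuac	q	ratio	direction	den_peptide	den_ratio	n_nonmod	nonmod_avg_ratio
1	P01042	KNG1	Kininogen-1	6	7	1	4	0.22	0.47	Down	LNAENN(de)ATFYFK	1.10	20	1.7
2	P01857	IGHG1	Immunoglobulin heavy constant gamma 1	4	5	1	1	0.20	2.18	Up	EEQYN(de)STYR	1.15	10	0.8
3	P01859	IGHG2	Immunoglobulin heavy constant gamma 2	4	4	1	0	0.20	0.49	Down	EEQFN(de)STFR	0.74	3	0.5
4	P01877	IGHA2	Immunoglobulin heavy constant alpha 2	5	3	1	0	0.20	1.58	Up	TPLTAN(de)ITK	0.68	2	1.3
5	P02760	AMBP	Protein AMBP	4	5	0	1	0.23	1.60	Up	YFYN(de)GTSMACETFQYGGCMGNGNNFVTEK	1.90	24	2.4
6	P02760	AMBP	Protein AMBP	5	6	0	0	0.23	2.47	Up	YFYN(de)GTSMACETFQYGGCMGNGNNFVTEK	1.90	24	2.4
7	P02760	AMBP	Protein AMBP	6	6	1	0	0.20	3.32	Up	YFYN(de)GTSMACETFQYGGCMGNGNNFVTEK	1.90	24	2.4
8	P02765	AHSG	Alpha-2-HS-glycoprotein	4	5	0	2	0.20	0.33	Down	AALAAFNAQNN(de)GSNFQLEEISR	1.38	8	1.7
9	P02765	AHSG	Alpha-2-HS-glycoprotein	4	6	1	0	0.20	2.56	Up	AALAAFNAQNN(de)GSNFQLEEISR	1.38	8	1.7
10	P02788	LTF	Lactotransferrin	4	7	0	1	0.23	0.51	Down	TAGWNIPMGLLFN(de)QTGSCK	0.52	23	0.7
11	P05090	APOD	Apolipoprotein D	7	6	0	0	0.24	1.40	Up	ADGTVNQIEGEATPVN(de)LTEPAK	2.78	6	0.6
12	P05155	SERPING1	Plasma protease C1 inhibitor	4	5	0	2	0.20	2.76	Up	ASSNPN(de)ATSSSSQDPESLQDR	0.92	5	1.5
13	P07911	UMOD	Uromodulin	5	7	0	3	0.20	0.35	Down	FALLMTNCYATPSSN(de)ATDPLK	0.87	29	1.4
14	P07911	UMOD	Uromodulin	4	6	0	1	0.20	0.14	Down	FALLMTNCYATPSSN(de)ATDPLK	0.87	29	1.4
15	P07911	UMOD	Uromodulin	5	4	0	1	0.20	0.30	Down	FALLMTNCYATPSSN(de)ATDPLK	0.87	29	1.4
16	P07911	UMOD	Uromodulin	6	7	0	3	0.23	0.46	Down	FALLMTNCYATPSSN(de)ATDPLK	0.87	29	1.4
17	P07911	UMOD	Uromodulin	6	7	0	2	0.25	0.54	Down	FALLMTNCYATPSSN(de)ATDPLK	0.87	29	1.4
18	P07911	UMOD	Uromodulin	6	5	1	3	0.20	0.58	Down	FALLMTNCYATPSSN(de)ATDPLK	0.87	29	1.4
19	P07911	UMOD	Uromodulin	9	4	1	0	0.20	0.76	Down	FALLMTNCYATPSSN(de)ATDPLK	0.87	29	1.4
20	P07911	UMOD	Uromodulin	7	6	0	0	0.20	1.55	Up	FALLMTNCYATPSSN(de)ATDPLK	0.87	29	1.4
21	P07911	UMOD	Uromodulin	5	6	0	2	0.23	0.59	Down	CNTAAPMWLN(de)GTHPSSDEGIVSR	1.03	29	1.4
22	P07911	UMOD	Uromodulin	5	6	1	3	0.20	0.19	Down	QDFN(de)ITDISLLEHR	1.16	29	1.4
23	P07911	UMOD	Uromodulin	6	7	0	4	0.20	0.48	Down	QDFN(de)ITDISLLEHR	1.16	29	1.4
24	P08185	SERPINA6	Corticosteroid-binding globulin	4	5	0	2	0.20	0.32	Down	AQLLQGLGFN(de)LTER	0.67
25	P10909	CLU	Clusterin	4	5	2	1	0.23	1.61	Up	LAN(de)LTQGEDQYYLR	0.80	6	1.6
26	P10909	CLU	Clusterin	5	6	0	3	0.20	3.01	Up	KEDALN(de)ETR	1.46	6	1.6
27	P10909	CLU	Clusterin	4	5	0	2	0.23	2.46	Up	EDALN(de)ETR	1.56	6	1.6
28	P13987	CD59	CD59 glycoprotein	2	2	0	0	0.23	1.48	Up	TAVN(de)CSSDFDACLITK	1.18	7	2.1
29	P13987	CD59	CD59 glycoprotein	5	5	1	1	0.22	1.54	Up	TAVN(de)CSSDFDACLITK	1.18	7	2.1
30	P13987	CD59	CD59 glycoprotein	4	5	0	2	0.21	1.67	Up	TAVN(de)CSSDFDACLITK	1.18	7	2.1
31	P13987	CD59	CD59 glycoprotein	5	5	1	0	0.22	1.70	Up	TAVN(de)CSSDFDACLITK	1.18	7	2.1
32	P13987	CD59	CD59 glycoprotein	4	6	1	1	0.23	1.71	Up	TAVN(de)CSSDFDACLITK	1.18	7	2.1
33	P13987	CD59	CD59 glycoprotein	5	5	1	1	0.25	1.73	Up	TAVN(de)CSSDFDACLITK	1.18	7	2.1
34	P13987	CD59	CD59 glycoprotein	5	5	1	0	0.24	1.73	Up	TAVN(de)CSSDFDACLITK	1.18	7	2.1
35	P13987	CD59	CD59 glycoprotein	4	6	1	1	0.24	1.78	Up	TAVN(de)CSSDFDACLITK	1.18	7	2.1
36	P13987	CD59	CD59 glycoprotein	4	6	2	0	0.24	1.91	Up	TAVN(de)CSSDFDACLITK	1.18	7	2.1
37	P28300	LOX	Protein-lysine 6-oxidase	4	5	1	2	0.20	2.43	Up	DPGAAVPGAAN(de)ASAQQPR	1.21	1	1.9
38	P28300	LOX	Protein-lysine 6-oxidase	4	6	2	0	0.20	2.82	Up	DPGAAVPGAAN(de)ASAQQPR	1.21	1	1.9
39	P28300	LOX	Protein-lysine 6-oxidase	4	5	1	1	0.23	1.84	Up	RDPGAAVPGAAN(de)ASAQQPR	1.54	1	1.9
40	P29622	SERPINA4	Kallistatin	4	5	0	1	0.21	0.34	Down	FLN(de)DTMAVYEAK	0.85
41	P29622	SERPINA4	Kallistatin	4	5	2	0	0.21	0.34	Down	FLN(de)DTMAVYEAK	0.85
42	P41222	PTGDS	Prostaglandin-H2 D-isomerase	5	7	0	2	0.25	0.45	Down	WFSAGLASN(de)SSWLR	0.34	8	2.0
43	P41222	PTGDS	Prostaglandin-H2 D-isomerase	4	5	1	2	0.20	0.32	Down	WFSAGLASN(de)SSWLR	0.34	8	2.0
44	P41222	PTGDS	Prostaglandin-H2 D-isomerase	5	6	2	0	0.20	0.63	Down	WFSAGLASN(de)SSWLR	0.34	8	2.0
45	P41222	PTGDS	Prostaglandin-H2 D-isomerase	5	6	1	3	0.21	0.47	Down	SVVAPATDGGLN(de)LTSTFLR	0.93	8	2.0
46	P41222	PTGDS	Prostaglandin-H2 D-isomerase	6	7	1	2	0.20	0.48	Down	SVVAPATDGGLN(de)LTSTFLR	0.93	8	2.0
47	P41222	PTGDS	Prostaglandin-H2 D-isomerase	5	7	1	1	0.22	0.64	Down	SVVAPATDGGLN(de)LTSTFLR	0.93	8	2.0
48	P41271	NBL1	Neuroblastoma suppressor of tumorigenicity 1	4	5	1	2	0.22	1.76	Up	N(de)ITQIVGHSGCEAK	1.24	1	3.6
49	Q07954	LRP1	Prolow-density lipoprotein receptor-related protein 1	2	2	1	0	0.24	1.97	Up	QSGDVTCN(de)CTDGR	1.65	2	1.9
50	Q14508	WFDC2	WAP four-disulfide core domain protein 2	5	7	0	3	0.20	1.95	Up	TGVCPELQADQN(de)CTQECVSDSECADNLK	1.30	6	1.6
51	Q14508	WFDC2	WAP four-disulfide core domain protein 2	4	6	0	1	0.22	1.90	Up	TGVCPELQADQN(de)CTQECVSDSECADNLK	1.30	6	1.6
52	Q14508	WFDC2	WAP four-disulfide core domain protein 2	6	3	1	2	0.20	2.12	Up	TGVCPELQADQN(de)CTQECVSDSECADNLK	1.30	6	1.6
53	Q6GTX8	LAIR1	Leukocyte-associated immunoglobulin-like receptor 1	5	6	1	1	0.24	2.10	Up	STYN(de)DTEDVSQASPSESEAR	0.96	2	1.8
54	Q6GTX8	LAIR1	Leukocyte-associated immunoglobulin-like receptor 1	4	5	1	1	0.21	2.16	Up	STYN(de)DTEDVSQASPSESEAR	0.96	2	1.8
55	Q96FE7	PIK3IP1	Phosphoinositide-3-kinase-interacting protein 1	4	6	0	2	0.23	0.65	Down	CLNWLDAQSGLASAPVSGAGN(de)HSYCR	0.57	6	1.7
56	Q96FE7	PIK3IP1	Phosphoinositide-3-kinase-interacting protein 1	5	6	1	3	0.25	0.63	Down	CLNWLDAQSGLASAPVSGAGN(de)HSYCR	0.57	6	1.7
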