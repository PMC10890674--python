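Cohort	Gene	Chromosome	Position	Father	Mother	Patient	PPH2 Score	PPH2 Prediction
Algerian	HISPPD1	5	chr5:102489584	G/G	G/G	G/A	1	probably damaging
Algerian	BTRC	10	chr10:103310478	G/G	G/G	G/A	1	probably damaging
Algerian	SKP2	5	chr5:36181963	G/G	G/G	G/A	1	probably damaging
Algerian	PUM1	1	chr1:31414074	G/G	G/G	A/G	1	probably damaging
Algerian	ZNF618	9	chr9:116811165	G/G	G/G	G/A	1	probably damaging
Algerian	PCDH19	X	chrX:99597014	C/C	C/C	T/T	1	probably damaging
Algerian	ACOX1	17	chr17:73944381	T/T	T/T	A/T	1	probably damaging
Algerian	ATP13A2	1	chr1:17318848	G/G	G/G	A/G	1	probably damaging
French	QTRT1	19	chr19:10822884	G/G	G/G	G/T	1	probably damaging
French	WDR53	3	chr3:196287910	G/G	G/G	A/G	1	probably damaging
French	MC3R	20	chr20:54824818	C/C	C/C	C/T	1	probably damaging
French	CES4	16	chr16:55806311	G/G	T/T	G/G	1	probably damaging
French	CSPP1	8	chr8:68070693	G/G	G/G	G/C	1	probably damaging
French	LEO1	15	chr15:52245429	C/C	C/C	G/C	1	probably damaging
French	CORO1C	12	chr12:109041222	C/C	C/C	C/T	1	probably damaging
Japanese	ABCC2	chr10	chr10:101611278	G/G	G/G	G/A	1	probably damaging
Algerian	LPHN1	19	chr19:14272190	G/G	G/G	G/A	0.999	probably damaging
French	KRT77	12	chr12:53086645	G/G	G/A	A/A	0.999	probably damaging
French	HLA-H	6	chr6:29855818	T/T	G/G	G/G	0.999	probably damaging
French	VEPH1	3	chr3:157177981	C/C	C/C	T/C	0.999	probably damaging
Japanese	ITGAM	chr16	chr16:31332562	C/C	C/C	C/T	0.999	probably damaging
Japanese	IL17B	chr5	chr5:148754050	G/G	G/G	G/A	0.999	probably damaging
Algerian	LPCAT1	5	chr5:1494826	G/G	G/G	G/A	0.997	probably damaging
Japanese	SECISBP2	chr9	chr9:91964831	C/C	C/C	C/T	0.997	probably damaging
French	NIN	14	chr14:51259598	G/G	G/G	T/G	0.996	probably damaging
Japanese	PRRG3	chrX	chrX:150869475	A/A	A/A	A/G	0.994	probably damaging
Algerian	GLI1	12	chr12:57864819	T/T	T/T	T/A	0.993	probably damaging
Japanese	DHRS9	chr2	chr2:169940028	G/G	G/G	G/A	0.993	probably damaging
French	SCUBE3	6	chr6:35207648	C/C	C/C	G/C	0.988	probably damaging
Japanese	GPR83	chr11	chr11:94113926	G/G	G/G	G/A	0.987	probably damaging
French	STK38L	12	chr12:27462071	A/A	A/A	G/A	0.985	probably damaging
Algerian	SRRM1	1	chr1:24977932	G/G	G/G	A/G	0.983	probably damaging
Algerian	POTEA	8	chr8:43157139	G/G	G/G	A/G	0.982	probably damaging
Japanese	MARK4	chr19	chr19:45790886	G/G	G/G	G/T	0.98	probably damaging
Algerian	OR4C11	11	chr11:55371021	T/T	G/G	T/T	0.977	probably damaging
French	IPO13	1	chr1:44415659	C/C	C/C	T/C	0.977	probably damaging
Algerian	MYH11	16	chr16:15820797	T/T	T/T	T/G	0.976	probably damaging
French	DNAH10	12	chr12:124359929	A/A	A/A	G/A	0.976	probably damaging
Japanese	HIPK2	chr7	chr7:139268761	C/C	C/C	C/T	0.972	probably damaging
Algerian	C11orf36	11	chr11:3243412	A/A	C/C	A/A	0.97	probably damaging
French	SPEN	1	chr1:16262042	C/C	C/C	T/C	0.969	probably damaging
Algerian	BTNL3	5	chr5:180420151	C/C	T/T	T/T	0.963	probably damaging
French	OR4S2	11	chr11:55418693	C/C	T/T	T/T	0.96	probably damaging
Algerian	OR4P4	11	chr11:55406157	A/A	G/G	A/A	0.959	probably damaging
Japanese	RBM14	chr11	chr11:66392695	G/G	G/G	G/A	0.959	probably damaging
Algerian	MYO1B	2	chr2:192228467	T/T	T/T	C/T	0.949	probably damaging
Japanese	GABRR1	chr6	chr6:89910913	T/T	T/T	T/C	0.948	probably damaging
Japanese	INTS3	chr1	chr1:153745469	G/G	G/G	G/A	0.947	probably damaging
Algerian	TTN	2	chr2:179585273	C/C	C/C	C/A	0.929	possibly damaging
Algerian	ADAMTS2	5	chr5:178634558	C/C	C/C	C/T	0.921	possibly damaging
Japanese	OR9G9	chr11	chr11:56468440	G/G	G/G	G/T	0.899	possibly damaging
Japanese	PRIM2	chr6	chr6:57512510	G/G	G/G	T/G	0.892	possibly damaging
Japanese	DNAH6	chr2	chr2:84848382	C/C	C/C	C/A	0.864	possibly damaging
Japanese	TCP11L2	chr12	chr12:106740187	A/A	A/A	A/G	0.823	possibly damaging
Japanese	KIAA1009	chr6	chr6:84910572	T/T	T/T	T/G	0.801	possibly damaging
Japanese	LAD1	chr1	chr1:201356296	C/C	C/C	C/T	0.783	possibly damaging
Japanese	RTTN	chr18	chr18:67691972	G/G	G/G	G/A	0.763	possibly damaging
Algerian	RYR3	15	chr15:33955901	G/G	G/G	G/A	0.718	possibly damaging
Japanese	CAST	chr5	chr5:96097979	A/A	A/A	A/T	0.708	possibly damaging
Japanese	DAB2	chr5	chr5:39392558	G/G	G/G	G/A	0.666	possibly damaging
Algerian	UHRF1	19	chr19:4941574	G/G	G/G	A/G	0.651	possibly damaging
Algerian	PCDHB9	5	chr5:140568167	A/A	T/T	T/T	0.645	possibly damaging
Japanese	SNED1	chr2	chr2:241976318	G/G	G/G	G/A	0.623	possibly damaging
Japanese	NACC1	chr19	chr19:13249035	G/G	G/G	G/A	0.569	possibly damaging
Japanese	FOXI1	chr5	chr5:169535610	G/G	G/G	G/A	0.556	possibly damaging
Algerian	NFIC	19	chr19:3381984	C/C	C/C	T/C	0.519	possibly damaging
Japanese	TRDN	chr6	chr6:123851705	G/G	G/G	G/A	0.478	possibly damaging
Japanese	CLSPN	chr1	chr1:36230927	C/C	C/C	C/A	0.414	benign
Japanese	FAM178A	chr10	chr10:102672962	C/C	C/C	C/T	0.398	benign
Algerian	ZIC1	3	chr3:147128576	T/T	T/T	C/T	0.391	benign
Algerian	ZNF548	19	chr19:57910901	A/A	A/A	G/A	0.33	benign
Japanese	DCAF4	chr14	chr14:73406575	C/C	C/C	C/T	0.205	benign
French	SKP2	5	chr5:36182122	A/A	A/A	C/A	0.181	benign
Japanese	CCAR1	chr10	chr10:70508947	G/G	G/G	G/A	0.162	benign
Japanese	VPS25	chr17	chr17:40931073	G/G	G/G	G/A	0.144	benign
Japanese	SPRED2	chr2	chr2:65559158	T/T	T/T	T/C	0.113	benign
Japanese	SMC1B	chr22	chr22:45767391	C/C	C/C	C/T	0.104	benign
French	RBM20	10	chr10:112572199	G/G	G/G	G/T	0.07	benign
Algerian	SPRY4	5	chr5:141694466	C/C	C/C	T/C	0.029	benign
French	ARHGAP21	10	chr10:24908686	C/C	T/T	C/C	0.013	benign
Algerian	VASN	16	chr16:4430931	G/G	G/G	A/G	0.004	benign
French	UGGT2	13	chr13:96665620	C/C	C/C	T/C	0.004	benign
Algerian	BTBD7	14	chr14:93709344	C/C	C/C	A/C	0.002	benign
Algerian	PCDHB9	5	chr5:140567445	A/A	A/G	G/G	0.001	benign
Algerian	SYNE1	6	chr6:152673248	T/T	T/T	T/C	0.001	benign
Algerian	SCNN1G	16	chr16:23200844	G/G	G/G	A/G	0.001	benign
Algerian	DSCR3	21	chr21:38612937	C/C	C/C	G/C	0	benign
Algerian	TNFRSF6B	20	chr20:62329635	G/G	G/G	A/G	0	benign
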