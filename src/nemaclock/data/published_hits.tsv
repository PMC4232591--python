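phylum	organism	query	clock_function	target	common_name	evalue	status
plant	Arabidopsis thaliana	CCA1	central clock	None		None	none
plant	Arabidopsis thaliana	COP1	LHY/CCA1 modulator	None		None	none
plant	Arabidopsis thaliana	DET1	LHY/CCA1 modulator	None		None	none
plant	Arabidopsis thaliana	GI	central clock	None		None	none
plant	Arabidopsis thaliana	LHY	central clock	None		None	none
plant	Arabidopsis thaliana	LUX	central clock	None		None	none
plant	Arabidopsis thaliana	PRR5	central clock	None		None	none
plant	Arabidopsis thaliana	PRR7	central clock	None		None	none
plant	Arabidopsis thaliana	PRR9	central clock	None		None	none
plant	Arabidopsis thaliana	TOC1	central clock	None		None	none
cyanobacteria	Synechococcus elongatus	KAI-A	central clock	None		None	none
cyanobacteria	Synechococcus elongatus	KAI-B	central clock	None		None	none
cyanobacteria	Synechococcus elongatus	KAI-C	central clock	None		None	none
fungus	Neurospora crassa	FRH	central clock	W08D2.7	MTR-4	0	accepted
fungus	Neurospora crassa	FRQ	central clock	None		None	none
fungus	Neurospora crassa	FWD-1	FRQ modulator	K10B2.1	LIN-23	1.2E-80	accepted
fungus	Neurospora crassa	VVD	central clock	F16B3.1	EGL-2	1.3E-06	accepted
fungus	Neurospora crassa	WC-1	central clock	F16B3.1	EGL-2	1.1E-05	accepted
fungus	Neurospora crassa	WC-2	central clock	F38A6.3d	HIF-1d	3.9E-10	accepted
insect	Drosophila melanogaster	PER	central clock	F47F6.1b	LIN-42b	2.10E-30	accepted
insect	Drosophila melanogaster	TIM	central clock	Y75B8A.22	TIM-1	3.20E-18	accepted
insect	Drosophila melanogaster	CLK	central clock	C25A1.11a	AHA-1a	1.70E-21	accepted
insect	Drosophila melanogaster	CYC	central clock	C25A1.11a	AHA-1a	4.10E-75	accepted
insect	Drosophila melanogaster	CRY	central clock	None		None	none
insect	Drosophila melanogaster	VRI	2nd loop	K08F8.2	ATF-2	1.70E-17	accepted
insect	Drosophila melanogaster	PDP1E	2nd loop	ZK909.4	CES-2	2.00E-06	accepted
insect	Drosophila melanogaster	CWO	3rd loop	None		None	none
insect	Drosophila melanogaster	CREB	Modulator	Y41C4A.4d	CRH-1d	8.10E-43	accepted
insect	Drosophila melanogaster	DBT	Modulator	C03C10.1	KIN-19	5.30E-190	accepted
insect	Drosophila melanogaster	CK2A	Modulator	B0205.7	KIN-3	3.50E-209	accepted
insect	Drosophila melanogaster	CK2B	Modulator	T01G9.6b	KIN-10	1.50E-121	accepted
insect	Drosophila melanogaster	SGG	Modulator	Y18D10A.5	GSK-3	3.30E-189	accepted
insect	Drosophila melanogaster	PP1b	Modulator	F29F11.6a	GSP-1a	1.30E-216	accepted
insect	Drosophila melanogaster	PP1-13C	Modulator	F56C9.1	GSP-2	1.30E-218	accepted
insect	Drosophila melanogaster	PP2a_MTS	Modulator	Y75B8A.30	PPH-4.1	3.90E-177	accepted
insect	Drosophila melanogaster	PP2a_TWS	Modulator	F26E4.1	SUR-6	4.00E-213	accepted
insect	Drosophila melanogaster	PP2a_WBT_A	Modulator	W08G11.4	PPTR-1	4.30E-256	accepted
insect	Drosophila melanogaster	PP2a_WBT_B	Modulator	C13G3.3c	PPTR-2c	9.50E-279	accepted
insect	Drosophila melanogaster	PRMT-5	Modulator	C34E10.5	PRMT-5	3.70E-144	accepted
insect	Drosophila melanogaster	SLMB	Modulator	K10B2.1	LIN-23	1.90E-232	accepted
insect	Drosophila melanogaster	RH1	Modulator	C52B11.3	DOP-4	8.60E-34	flagged
insect	Drosophila melanogaster	RH5	Modulator	C52B11.3	DOP-4	4.00E-30	flagged
insect	Drosophila melanogaster	RH6	Modulator	C52B11.3	DOP-4	8.40E-30	flagged
insect	Drosophila melanogaster	NMO	Modulator	W06F12.1e	LIT-1e	1.50E-182	accepted
insect	Drosophila melanogaster	NOCTE	Modulator	None		None	none
insect	Drosophila melanogaster	NORPA	Modulator	B0348.4a	EGL8a	0	accepted
insect	Drosophila melanogaster	TO	Output	None		None	none
insect	Drosophila melanogaster	PDF	Output	T07E3.6b	PDF-1	3.00E-02	accepted
insect	Drosophila melanogaster	PDFR	Output	C13B9.4a	PDFR-1a	1.80E-127	accepted
insect	Drosophila melanogaster	SLO	Output	Y51A2D.19a	SLO-1a	0	accepted
insect	Drosophila melanogaster	NA	Output	C11D2.6a	UNC-77a	0	accepted
insect	Drosophila melanogaster	IR	Output	M02A10.2a	IRK-2a	8.50E-159	accepted
insect	Drosophila melanogaster	JET	Output	C02F5.7a		8.80E-128	accepted
insect	Drosophila melanogaster	CSN4	Output	Y55F3AM.15	CSN-4	7.80E-85	accepted
insect	Drosophila melanogaster	PKA	Output	ZK909.2h	KIN-1h	1.60E-217	accepted
insect	Drosophila melanogaster	EBONY	Output	Y66D12A.14		1.40E-60	flagged
insect	Drosophila melanogaster	LRK	Output	F18H3.3b	PAB-2b	1.80E-36	accepted
insect	Drosophila melanogaster	FER2	Output	B0304.1b	HLH-1b	1.90E-12	accepted
insect	Drosophila melanogaster	JAFRAC	Output	F09E5.15a	PRDX-2a	5.10E-105	accepted
insect	Drosophila melanogaster	WDS-PB	Output	C14B1.4	WDR-5.1	3.50E-165	accepted
mammal	Mus musculus	PER1	central clock	F47F6.1c	LIN-42c	7.50E-17	accepted
mammal	Mus musculus	PER2	central clock	F47F6.1b	LIN-42b	2.90E-21	accepted
mammal	Mus musculus	PER3	central clock	F47F6.1b	LIN-42b	5.50E-20	accepted
mammal	Mus musculus	BMAL1	central clock	C25A1.11a	AHA-1a	1.80E-65	accepted
mammal	Mus musculus	BMAL2	central clock	C25A1.11a	AHA-1a	5.40E-63	accepted
mammal	Mus musculus	CLK	central clock	C25A1.11a	AHA-1a	1.50E-17	accepted
mammal	Mus musculus	NPAS2	central clock	C25A1.11a	AHA-1a	6.80E-19	accepted
mammal	Mus musculus	CRY1	central clock	None		None	none
mammal	Mus musculus	CRY2	central clock	None		None	none
mammal	Mus musculus	ROR-A	2nd loop	C01H6.5b	NHR-23b	1.40E-70	accepted
mammal	Mus musculus	ROR-B	2nd loop	C01H6.5a	NHR-23a	4.50E-73	accepted
mammal	Mus musculus	NR1D1	2nd loop	W05B5.3a	NHR-85a	8.10E-47	accepted
mammal	Mus musculus	NR1D2	2nd loop	W05B5.3a	NHR-85a	8.70E-55	accepted
mammal	Mus musculus	DBP	3rd loop	ZK909.4	CES-2	1.50E-18	accepted
mammal	Mus musculus	CSNK1a	Modulator	C03C10.1	KIN-19	4.30E-204	accepted
mammal	Mus musculus	CSNK1d	Modulator	F46F2.2b	KIN-20b	1.40E-172	accepted
mammal	Mus musculus	CSNK1e	Modulator	F46F2.2b	KIN-20b	5.00E-172	accepted
mammal	Mus musculus	CCRN4L	Modulator	ZC518.3c	CCR-4c	3.50E-21	accepted
mammal	Mus musculus	DEC1	Modulator	Y54G2A.1	LIN-22	4.20E-05	flagged
mammal	Mus musculus	DEC2	Modulator	Y54G2A.1	LIN-22	1.50E-05	flagged
mammal	Mus musculus	FBXL-3	Modulator	C02F5.7a		5.20E-04	accepted
mammal	Mus musculus	PPARGC1a	Modulator	F18H3.3b	PAB-2b	6.10E-08	flagged
mammal	Mus musculus	MEL1A	Output	F41E7.3	NPR-6	1.00E-26	accepted
mammal	Mus musculus	MEL1B	Output	F41E7.3	NPR-6	1.10E-31	accepted
mammal	Mus musculus	OPN4	Input	T11B7.4e	ALP-1e	5.20E-61	flagged
mammal	Mus musculus	PKC2	Output	None		None	none
mammal	Mus musculus	VIP	Output	None		None	none
mammal	Mus musculus	VPAC2	Output	C18B12.2	SEB-3	1.60E-37	accepted
mammal	Mus musculus	PRDX-2	Output	F09E5.15a	PRDX-2a	1.70E-104	accepted
mammal	Mus musculus	WD-REP	Output	C14B1.4	WDR-5.1	2.70E-159	accepted
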