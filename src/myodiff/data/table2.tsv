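group	direction	rank	gene
DM	over	1	TNFSF10
DM	over	2	GDF15
DM	over	3	CXCL11
DM	over	4	IL1RN
DM	over	5	IFNB1
DM	over	6	TNFSF18
DM	over	7	CCL8
DM	over	8	IL15RA
DM	over	9	CCL19
DM	over	10	CXCL10
DM	over	11	TNFSF13B
DM	over	12	IL22RA1
DM	over	13	IL18
DM	over	14	CCL11
DM	over	15	IL12RB2
DM	over	16	CD80
DM	over	17	CCL7
DM	over	18	CCR1
DM	over	19	AREG
DM	over	20	GRN
DM	over	21	TNFRSF1A
DM	over	22	CCL2
DM	over	23	IL27
DM	over	24	ACKR4
DM	over	25	IFNGR1
DM	over	26	TNFRSF10B
DM	over	27	TNFRSF12A
DM	over	28	ITGA5
DM	over	29	TNFRSF6B
DM	over	30	IL1RL1
DM	over	31	IL10
DM	over	32	CCRL2
DM	over	33	CSF1
DM	over	34	IL18BP
DM	over	35	IL18R1
DM	over	36	TNFRSF13C
DM	over	37	CD86
DM	over	38	TNFRSF21
DM	over	39	EDA2R
DM	over	40	IL1RL2
DM	over	41	PDCD1LG2
DM	over	42	CXCL16
DM	over	43	OSMR
DM	over	44	IL12A
DM	over	45	BMP1
DM	over	46	CD40
DM	over	47	TGFB3
DM	over	48	CXCL1
DM	over	49	IL1R1
DM	under	1	BMP6
Mi2	over	1	IL11
Mi2	over	2	GDF11
Mi2	over	3	TNFSF10
Mi2	over	4	IL1RN
Mi2	over	5	GDF15
Mi2	over	6	GRN
Mi2	over	7	IL1RAP
Mi2	over	8	CCL11
Mi2	over	9	TNFSF9
Mi2	over	10	CCL8
Mi2	over	11	CXCL11
Mi2	over	12	TNFRSF21
Mi2	over	13	CCRL2
Mi2	over	14	TNFSF18
Mi2	over	15	TNFRSF1A
Mi2	over	16	IL27
MDA5	over	1	TNFSF10
NXP2	over	1	GDF15
NXP2	over	2	IFNB1
NXP2	over	3	IL1RN
NXP2	over	4	TNFSF10
NXP2	over	5	CXCL11
NXP2	over	6	TNFSF18
NXP2	over	7	IL15RA
NXP2	over	8	IL18
NXP2	over	9	IL22RA1
NXP2	over	10	NAMPT
NXP2	over	11	IL12RB2
NXP2	over	12	IL1RL1
NXP2	over	13	CXCL10
NXP2	over	14	CCL7
NXP2	over	15	CCL8
TIF1	over	1	GDF15
TIF1	over	2	CXCL11
TIF1	over	3	TNFSF10
TIF1	over	4	CCL19
TIF1	over	5	TNFSF18
TIF1	over	6	IL31RA
IMNM	over	1	SPP1
IMNM	over	2	IL17B
IMNM	over	3	IL13RA1
IMNM	over	4	OSMR
IMNM	over	5	IL10RB
IMNM	over	6	CMTM7
IMNM	over	7	MIF
IMNM	over	8	IFNGR1
IMNM	over	9	TGFB3
IMNM	under	1	CD274
HMGCR	over	1	IL17B
HMGCR	over	2	IL10RB
HMGCR	over	3	SPP1
HMGCR	over	4	IL13RA1
HMGCR	under	1	CD274
HMGCR	under	2	CNTFR
SRP	over	1	SPP1
ASyS	over	1	CXCL8
ASyS	over	2	CXCL9
ASyS	over	3	TNFSF14
ASyS	over	4	CCL20
ASyS	over	5	CXCL1
ASyS	over	6	CD28
Jo1	over	1	CXCL9
Jo1	over	2	CXCL8
Jo1	over	3	TNFSF14
Jo1	over	4	CXCL13
Jo1	over	5	SPP1
Jo1	over	6	CCL19
Jo1	over	7	CXCL1
Jo1	over	8	CXCL10
Jo1	over	9	CCL20
Jo1	over	10	CCL4L2
Jo1	over	11	CCL3L3
Jo1	over	12	CXCL11
Jo1	over	13	CD27
Jo1	over	14	CCL8
Jo1	over	15	TNFRSF9
Jo1	over	16	CD28
Jo1	over	17	IL1RL1
Jo1	over	18	IL18BP
Jo1	over	19	CCL4
Jo1	over	20	FASLG
Jo1	over	21	CCL2
Jo1	over	22	CCL13
Jo1	over	23	CCL3
Jo1	over	24	CSF2
Jo1	over	25	IFNG
Jo1	over	26	IL12RB1
Jo1	over	27	IL2RG
IBM	over	1	CCL5
IBM	over	2	CD27
IBM	over	3	CXCR3
IBM	over	4	IL2RG
IBM	over	5	CXCL9
IBM	over	6	CCR5
IBM	over	7	IFNG
IBM	over	8	ITGA4
IBM	over	9	CCL13
IBM	over	10	XCL1
IBM	over	11	XCL2
IBM	over	12	CXCR6
IBM	over	13	FAS
IBM	over	14	TNFRSF17
IBM	over	15	CTLA4
IBM	over	16	IL7R
IBM	over	17	TNFRSF13B
IBM	over	18	CCR2
IBM	over	19	IL5RA
IBM	over	20	IL12B
IBM	over	21	CD40LG
IBM	over	22	CCL18
IBM	over	23	TNFSF14
IBM	over	24	IL2RB
IBM	over	25	CXCL13
IBM	over	26	PDCD1LG2
IBM	over	27	FASLG
IBM	over	28	IL16
IBM	over	29	CCR4
IBM	over	30	IL12RB1
IBM	over	31	IL21R
IBM	over	32	CCL17
IBM	over	33	IL10RA
IBM	over	34	CCR8
IBM	over	35	XCR1
IBM	over	36	CXCR5
IBM	over	37	FLT3LG
IBM	over	38	TNFRSF9
IBM	over	39	CXCR4
IBM	over	40	IL7
IBM	over	41	FLT3
IBM	over	42	IL21
IBM	over	43	CCL22
IBM	over	44	LTA
IBM	over	45	CCL4
IBM	over	46	CXCL10
IBM	over	47	CD80
IBM	over	48	TNFSF13B
IBM	over	49	TNF
IBM	over	50	TNFSF8
IBM	over	51	PDCD1
IBM	over	52	GDF11
IBM	over	53	CD40
IBM	over	54	BMP10
IBM	over	55	TNFRSF13C
IBM	over	56	CCR7
IBM	over	57	CCL19
IBM	over	58	CSF2RA
IBM	over	59	IL18BP
IBM	over	60	CXCL11
IBM	over	61	CD86
IBM	over	62	TNFRSF1B
IBM	over	63	CCL26
IBM	over	64	CD70
IBM	over	65	IL17RA
IBM	over	66	ITGA9
IBM	over	67	BMP8B
IBM	over	68	IL27
IBM	over	69	CSF1R
IBM	over	70	SIGIRR
IBM	over	71	TNFRSF14
IBM	under	1	CRLF1
IBM	under	2	CTF1
IBM	under	3	NAMPT
PM/Scl	over	1	TNFRSF25
PM/Scl	over	2	TNFRSF4
PM/Scl	over	3	CXCL13
PM/Scl	over	4	LTB
PM/Scl	over	5	CD27
PM/Scl	over	6	CXCR5
PM/Scl	over	7	TNFRSF9
PM/Scl	over	8	CXCL9
PM/Scl	over	9	PDCD1
PM/Scl	over	10	CCL19
PM/Scl	over	11	CCR7
PM/Scl	over	12	TNFRSF14
PM/Scl	over	13	CX3CL1
PM/Scl	over	14	FLT3LG
PM/Scl	over	15	TNFRSF13C
PM/Scl	over	16	CTLA4
PM/Scl	over	17	EBI3
PM/Scl	over	18	LTA
PM/Scl	over	19	TNFRSF18
PM/Scl	over	20	CCR4
PM/Scl	over	21	IL2RB
PM/Scl	over	22	CCL4L2
PM/Scl	over	23	IL27RA
PM/Scl	over	24	CXCR3
PM/Scl	over	25	CXCR6
PM/Scl	over	26	IL3RA
PM/Scl	under	1	TSLP
NT	over	1	AIMP1
NT	over	2	MSTN
NT	over	3	IFNAR1
NT	over	4	GPI
NT	over	5	TSLP
NT	over	6	ACVR1
NT	over	7	ITGB6
NT	over	8	BMPR1A
NT	over	9	IL17D
NT	over	10	ACVR2B
NT	over	11	IFNA1
NT	under	1	TNFRSF14
NT	under	2	ITGA5
NT	under	3	IL4R
NT	under	4	CCL4L2
NT	under	5	BMP1
NT	under	6	CCL3
NT	under	7	CSF1
NT	under	8	LTBR
NT	under	9	PDCD1
NT	under	10	CCL4
NT	under	11	TNFRSF1B
NT	under	12	IL17RA
NT	under	13	TNFSF13
NT	under	14	ACKR1
NT	under	15	CMTM7
NT	under	16	IL21R
NT	under	17	TGFB1
NT	under	18	TNFRSF21
NT	under	19	TNFRSF18
NT	under	20	CCL19
NT	under	21	TNFRSF10B
NT	under	22	GRN
NT	under	23	IL2RA
NT	under	24	TNFSF8
NT	under	25	OSMR
NT	under	26	IL7
NT	under	27	CCL18
NT	under	28	GDF15
NT	under	29	CXCL13
NT	under	30	NGFR
NT	under	31	IL1RN
NT	under	32	SIGIRR
NT	under	33	TNFRSF12A
NT	under	34	CD28
NT	under	35	CCL8
NT	under	36	CD80
NT	under	37	TNFRSF4
NT	under	38	IL18BP
NT	under	39	IL10RA
NT	under	40	TNFSF13B
NT	under	41	TGFBR2
NT	under	42	CMTM3
NT	under	43	CCL21
NT	under	44	IFNG
NT	under	45	CXCL11
NT	under	46	CCL13
NT	under	47	IL12RB1
NT	under	48	CKLF
NT	under	49	CX3CL1
NT	under	50	TNFSF14
NT	under	51	IL10
NT	under	52	IL34
NT	under	53	CD86
NT	under	54	IL1RL1
NT	under	55	LTA
NT	under	56	FLT3LG
NT	under	57	LTB
NT	under	58	IL27
NT	under	59	CCL3L3
NT	under	60	ENSG00000198223.17
NT	under	61	EBI3
NT	under	62	IL2RG
NT	under	63	IL18RAP
NT	under	64	CXCL10
NT	under	65	SPP1
NT	under	66	EDA2R
NT	under	67	CSF2RB
NT	under	68	CCL2
NT	under	69	TNFRSF10A
NT	under	70	IL6
NT	under	71	CLCF1
NT	under	72	CTLA4
NT	under	73	CCRL2
NT	under	74	TNFRSF25
NT	under	75	CXCR4
NT	under	76	CCR5
NT	under	77	IL23A
NT	under	78	CXCR6
NT	under	79	LIF
NT	under	80	CXCL16
NT	under	81	GDF6
NT	under	82	GDF5
NT	under	83	FAS
NT	under	84	TNFSF9
NT	under	85	AREG
NT	under	86	CSF3R
NT	under	87	IL15RA
NT	under	88	ITGA4
NT	under	89	CCR1
NT	under	90	MIF
NT	under	91	IL1R1
NT	under	92	IL18R1
NT	under	93	FASLG
NT	under	94	IL17B
NT	under	95	C1QTNF4
NT	under	96	TNFSF4
NT	under	97	TNFRSF9
NT	under	98	IL27RA
NT	under	99	TNFRSF10C
NT	under	100	CCL5
NT	under	101	ALKAL2
NT	under	102	CD27
NT	under	103	TNFRSF17
NT	under	104	TNFRSF13B
NT	under	105	CSF1R
NT	under	106	TNF
NT	under	107	TNFRSF11B
NT	under	108	OSM
NT	under	109	IL32
NT	under	110	IL7R
NT	under	111	IL1RL2
NT	under	112	CXCR3
NT	under	113	CCL11
NT	under	114	CXCL9
NT	under	115	CCL23
NT	under	116	GDF11
NT	under	117	CCL20
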