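group	direction	rank	gene
DM	over	1	TNFSF10
DM	over	2	GDF15
DM	over	3	IL1RN
DM	over	4	IFNB1
DM	over	5	TNFSF18
DM	over	6	IL15RA
DM	over	7	IL22RA1
DM	over	8	IL18
DM	over	9	CCL11
DM	over	10	IL12RB2
DM	over	11	CCL7
DM	over	12	CCR1
DM	over	13	AREG
DM	over	14	GRN
DM	over	15	TNFRSF1A
DM	over	16	ACKR4
DM	over	17	TNFRSF10B
DM	over	18	TNFRSF12A
DM	over	19	ITGA5
DM	over	20	TNFRSF6B
DM	over	21	IL10
DM	over	22	CCRL2
DM	over	23	CSF1
DM	over	24	IL18R1
DM	over	25	TNFRSF21
DM	over	26	EDA2R
DM	over	27	IL1RL2
DM	over	28	CXCL16
DM	over	29	IL12A
DM	over	30	BMP1
DM	over	31	IL1R1
DM	under	1	BMP6
Mi2	over	1	IL11
Mi2	over	2	GRN
Mi2	over	3	IL1RAP
Mi2	over	4	CCL11
Mi2	over	5	TNFSF9
Mi2	over	6	TNFRSF21
Mi2	over	7	CCRL2
Mi2	over	8	TNFRSF1A
NXP2	over	1	IFNB1
NXP2	over	2	IL15RA
NXP2	over	3	IL18
NXP2	over	4	IL22RA1
NXP2	over	5	NAMPT
NXP2	over	6	IL12RB2
NXP2	over	7	CCL7
TIF1	over	1	IL31RA
IMNM	over	1	IL17B
IMNM	over	2	IL13RA1
IMNM	over	3	IL10RB
IMNM	over	4	CMTM7
IMNM	over	5	MIF
IMNM	under	1	CD274
HMGCR	over	1	IL17B
HMGCR	over	2	IL10RB
HMGCR	over	3	IL13RA1
HMGCR	under	1	CD274
HMGCR	under	2	CNTFR
ASyS	over	1	CXCL8
ASyS	over	2	CCL20
ASyS	over	3	CD28
Jo1	over	1	CXCL8
Jo1	over	2	CCL20
Jo1	over	3	CCL3L3
Jo1	over	4	CD28
Jo1	over	5	CCL3
Jo1	over	6	CSF2
IBM	over	1	CCL5
IBM	over	2	CCR5
IBM	over	3	ITGA4
IBM	over	4	XCL1
IBM	over	5	XCL2
IBM	over	6	FAS
IBM	over	7	TNFRSF17
IBM	over	8	IL7R
IBM	over	9	CCR2
IBM	over	10	IL5RA
IBM	over	11	IL12B
IBM	over	12	CD40LG
IBM	over	13	CCL18
IBM	over	14	IL16
IBM	over	15	IL21R
IBM	over	16	CCL17
IBM	over	17	IL10RA
IBM	over	18	CCR8
IBM	over	19	XCR1
IBM	over	20	CXCR4
IBM	over	21	IL7
IBM	over	22	FLT3
IBM	over	23	IL21
IBM	over	24	CCL22
IBM	over	25	TNFSF13B
IBM	over	26	TNF
IBM	over	27	TNFSF8
IBM	over	28	BMP10
IBM	over	29	CSF2RA
IBM	over	30	TNFRSF1B
IBM	over	31	CCL26
IBM	over	32	CD70
IBM	over	33	IL17RA
IBM	over	34	ITGA9
IBM	over	35	BMP8B
IBM	over	36	CSF1R
IBM	over	37	SIGIRR
IBM	under	1	CRLF1
IBM	under	2	CTF1
IBM	under	3	NAMPT
PM/Scl	over	1	TNFRSF25
PM/Scl	over	2	TNFRSF4
PM/Scl	over	3	LTB
PM/Scl	over	4	CX3CL1
PM/Scl	over	5	EBI3
PM/Scl	over	6	TNFRSF18
PM/Scl	over	7	IL27RA
PM/Scl	over	8	IL3RA
PM/Scl	under	1	TSLP
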