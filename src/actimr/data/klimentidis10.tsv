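SNP	effect_allele	other_allele	chr	position	gene	eaf	beta	se	n
rs12045968	G	T	1	33225097	ZNF362	0.22	0.24	0.044	91084
rs34517439	C	A	1	77984833	DNAJB4	0.91	0.31	0.056	91084
rs6775319	A	T	3	18717009	LOC105376976	0.30	0.23	0.041	91084
rs12522261	G	A	5	152675265	LINC01470	0.67	0.21	0.038	91084
rs9293503	T	C	5	88653144	LINC00461	0.88	0.33	0.059	91084
rs11012732	A	G	10	21541175	MLLT10	0.65	0.23	0.039	91084
rs148193266	C	A	11	104657953	RP11-681H1.1	0.02	0.51	0.092	91084
rs1550435	T	C	15	74039044	PML	0.53	0.20	0.037	91084
rs55657917	G	T	17	45767194	CRHR1	0.22	0.30	0.040	91084
rs59499656	T	A	18	43188344	RIT2/SYT4	0.34	0.23	0.038	91084
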