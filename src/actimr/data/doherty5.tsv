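SNP	effect_allele	other_allele	chr	position	gene	eaf	beta	se	n
rs6775319	A	T	3	18717009	SATB1-AS1	0.27	0.03	0.005	91105
rs6895232	T	A	5	152659861	LINC01470	0.66	0.03	0.005	91105
rs564819152	A	G	10	21531721	SKIDA1	0.68	0.03	0.005	91105
rs2696625	G	A	17	46249498	KANSL1-AS1	0.23	0.04	0.005	91105
rs59499656	T	A	18	43188344	RIT2/SYT4	0.35	0.03	0.005	91105
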