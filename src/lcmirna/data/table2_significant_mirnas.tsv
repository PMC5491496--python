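mirbase_acc	plate	assay_id	fold_change	p_value	regulation	chromosome	strand	seed
MIMAT0000070	A	hsa-miR-17-5p	1.260715355	0.012752	up	13	sense	AAAGUGC
MIMAT0001413	A	hsa-miR-20b-5p	1.248312981	0.038056	up	X	antisense	AAAGUGC
MIMAT0000103	A	hsa-miR-106a-5p	1.2312043	0.036205	up	X	antisense	AAAGUGC
MIMAT0000751	A	hsa-miR-330-3p	1.403274751	0.010941	up	19	antisense	CAAAGCA
MIMAT0001638	A	hsa-miR-409-5p	0.780180155	0.039303	down	14	sense	GGUUACC
MIMAT0004920	A	hsa-miR-541-3p	1.520180479	0.024907	up	14	sense	GGUGGGC
MIMAT0003247	A	hsa-miR-582-5p	1.430205029	0.022995	up	5	antisense	UACAGUU
MIMAT0004912	A	hsa-miR-890	1.335886765	0.020283	up	X	antisense	ACUUGGA
MIMAT0004584	B	hsa-let-7g-3p	0.56503572	0.021121	down	3	antisense	GAGGUAG
MIMAT0004678	B	hsa-miR-99b-3p	1.398655254	0.039436	up	19	sense	ACCCGUA
MIMAT0004800	B	hsa-miR-550-5p	1.576943392	0.041171	up	7	sense	GUGCCUG
MIMAT0005824	B	hsa-miR-1179	1.550548092	0.018529	up	15	sense	AGCAUUC
MIMAT0005955	B	hsa-miR-1197	0.4863239	0.00846	down	14	sense	AGGACAC
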