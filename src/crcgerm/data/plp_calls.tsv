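penetrance	category	gene	transcript	hgvs_c	hgvs_p	rsid	zygosity	variant_type	classification	criteria
high	diagnostic	BMPR1A	NM_004329.3	c.176T>A	p.Leu59Ter	rs1564714834	het	missense	pathogenic	PVS1 + PM2 + PM4 + BP1
high	diagnostic	MLH1	NM_000249.4	c.1039delA	p.Thr347Leufs*20	.	het	lof	likely_pathogenic	PVS1 + PM2
high	diagnostic	MSH6	NM_000179.3	c.3516_3517delAG	p.Arg1172Serfs*4	rs398123232	het	lof	pathogenic	PVS1 + PM2 + PM4
high	diagnostic	PTCH1	NM_000264.5	c.3241G>A	p.Val1081Met	rs587778629	het	missense	likely_pathogenic	PS3 + PM2 + PP3
less_well_defined	diagnostic	FLCN	NM_144997.7	c.1285delC	p.His429Thrfs*39	rs80338682	het	lof	likely_pathogenic	PVS1 + PM2
less_well_defined	diagnostic	NOTCH3	NM_000435.3	c.1345C>T	p.Arg449Cys	rs762734007	het	missense	likely_pathogenic	PM1 + PM2 + PP2 + PP3
less_well_defined	diagnostic	NTHL1	NM_002528.7	c.244C>T	p.Gln82Ter	rs150766139	het	lof	pathogenic	PVS1 + PM2 + PM4
moderate	diagnostic	BARD1	NM_000465.4	c.2229dupT	p.Asn744Ter	rs1259296823	het	lof	pathogenic	PVS1 + PM1 + PM2 + PM4
less_well_defined	candidate	ERCC1	NM_202001.3	c.702+1G>A	.	rs747911302	het	splice	likely_pathogenic	PVS1 + PM2
less_well_defined	candidate	EXO1	NM_130398.4	c.1465delA	p.Arg489Glyfs*32	.	het	lof	likely_pathogenic	PVS1 + PM2
less_well_defined	candidate	IL12RB1	NM_005535.3	c.1791+2T>G	.	rs554063682	het	splice	pathogenic	PVS1 + PM2 + PP3
less_well_defined	candidate	OGG1	NM_002542	c.137G>A	p.Arg46Gln	rs104893751	het	missense	likely_pathogenic	PS3 + PM2
less_well_defined	candidate	SMAD9	NM_001127217.3	c.781+2T>A	.	rs770716081	het	splice	likely_pathogenic	PVS1 + PM2 + BP4
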