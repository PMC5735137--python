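subject_id	gene	chrom	g_pos	exon	hgvs_c	hgvs_p	band	maf_1000g	maf_esp	maf_exac	sift	mutation_taster	polyphen_hvar	polyphen_hdiv	zygosity	ddg
CCF00162	TTN	chr2	179446909	315	c.66187G>C	p.V22063L	A-band	0	0	0.0001008	damaging	damaging	damaging	damaging	het	-1.30
CCF02011	TTN	chr2	179543195	144	c.33856G>A	p.E11286K	I-band	0	0.000084	0.0005749	damaging	damaging	damaging	damaging	het	-0.81
CCF06949	TTN	chr2	179574497	99	c.28549G>A	p.V9517M	I-band	0	0	0	damaging	damaging	damaging	damaging	het	-2.09
CCF07265	TTN	chr2	179413865	339	c.92488G>A	p.V30830I	A-band	0	0.000164	2.49e-05	damaging	damaging	damaging	damaging	het	-1.09
CCF06673	TTN	chr2	179584872	81	c.23497G>C	p.G7833R	I-band	0	0	4.149e-05	damaging	damaging	damaging	damaging	het	-1.32
CCF01021	TTN	chr2	179599265	52	c.15286T>C	p.C5096R	I-band	0	0	0	damaging	damaging	damaging	damaging	het	-1.47
CCF02423	TTN	chr2	179571284	102	c.29317G>A	p.A9773T	I-band	0	0.000165	5.797e-05	damaging	damaging	damaging	damaging	het	-0.73
CCF07445	TTN	chr2	179442383	323	c.68770G>A	p.A22924T	A-band	0	0	0	damaging	damaging	damaging	damaging	het	-0.84
CCF07445	TTN	chr2	179396767	358	c.104575C>T	p.R34859W	M-band	0	0	0	damaging	damaging	damaging	damaging	het	-0.49
CCF02153	TTN	chr2	179650807	14	c.2138G>A	p.R713Q	Z-disk	0	0	1.66e-05	damaging	damaging	damaging	damaging	het	-0.65
CCF06523	TTN	chr2	179403402	354	c.99154C>T	p.R33052C	A-band	0	0	4.141e-05	damaging	damaging	damaging	damaging	het	-1.00
CCF02289	TTN	chr2	179396361	358	c.104981G>A	p.S34994N	M-band	0	0	0	damaging	damaging	damaging	damaging	het	-1.41
CCF08133	TTN	chr2	179430434	305	c.80425G>A	p.G26809S	A-band	0	0.000081	0.0002154	damaging	damaging	damaging	damaging	het	-0.67
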