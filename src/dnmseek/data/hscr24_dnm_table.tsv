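trio	phenotype	gene	hgvs_c	hgvs_p	type	maf_dbsnp	maf_esp	maf_exac	mosaic
1	L,F	RET	3splicing9+1	.	Splicing	N	N	N	0
1	L,F	RBM25	c.474C>T	p.L158L	Synonymous	N	N	N	0
2	L,F	RET	c.2511_2519delCCCTGGACC	p.S837fs	Frameshift	N	N	N	0
2	L,F	COL6A3	c.3327C>T	p.H1109H	Synonymous	4.2E-4	N	1.2E-4	0
3	L,F	RET	c.1818_1819insGGCAC	p.Y606fs	Frameshift	N	N	N	0
4	L,F	DAB2IP	c.2339C>T	p.T780M	Missense	N	N	2.8E-3	1
4	L,F	ISG20L2	c.961G>A	p.G321R	Missense	N	N	N	0
4	L,F	MED26	c.675C>T	p.A225A	Synonymous	N	N	N	0
4	L,F	NCLN	c.496C>T	p.Q166X	Nonsense	N	N	N	1
4	L,F	NUP98	c.5207A>G	p.N1736S	Missense	N	N	N	0
4	L,F	VEZF1	c.584C>T	p.S195F	Missense	N	N	N	0
4	L,F	ZNF57	c.570C>T	p.D190D	Synonymous	N	N	N	0
5	L,F	RET	c.1761delG	p.G588fs	Frameshift	N	N	N	0
5	L,F	SCUBE3	c.1493A>T	p.N498I	Missense	N	N	N	0
6	L,M	AFF3	c.1975G>C	p.V659L	Missense	N	N	N	0
6	L,M	PLEKHG5	c.2628G>T	p.T876T	Synonymous	N	N	9.1E-6	0
7	L,M	KDM4A	c.26A>G	p.N9S	Missense	N	N	N	0
8	L,M	MAP4	c.3351C>T	p.G1117G	Synonymous	N	N	9.2E-6	0
9	L,F	RET	c.1858T>C	p.C620R	Missense	0	N	N	0
10	TCA,M	CKAP2L	c.555_556delAA	p.E186fs	Frameshift	N	2E-5	2.5E-5	0
11	L,F	RET	c.409T>G	p.C137G	Missense	N	N	N	0
11	L,F	HMCN1	c.10366G>A	p.A3456T	Missense	N	N	N	0
11	L,F	TUBG1	c.699T>C	p.S233S	Synonymous	N	N	8.2E-6	0
12	L,F	CCR2	c.848T>A	p.L283Q	Missense	N	N	N	0
12	L,F	DENND3	c.1921delT	p.K640fs	Frameshift	N	N	N	0
13	L,F	RET	c.1710C>A	p.C570X	Nonsense	N	N	N	0
14	L,F	RET	c.526_528delGCA	p.R175del	Non-frameshift	N	N	N	0
14	L,F	TBATA	c.157C>T	p.R53C	Missense	N	N	4.1E-5	0
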