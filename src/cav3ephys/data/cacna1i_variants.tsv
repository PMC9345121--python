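sample_ids	locus	aa_change	coding	sift	polyphen2	lrt	mutation_taster	fathmm	cadd	gnomad_nfe_maf	ukbiobank_maf	case_maf	rsid
DGR211	chr22:39994250	p.R111G	c.331C>G	D	P	N	D	D	34	9.84E-06	2.23E-05	0.0026738	rs751729397
DGR1,DGR239	chr22:39996558	p.M128L	c.382A>C	T	B	D	N	D	9.094	0.0006	0.00071	0.00534759	rs58395851
DGR32	chr22:40037036	p.D302G	c.905A>G	T	B	U	N	D	23.6	0.0013	0.001	0.0026738	rs59635914
DGR246	chr22:40037051	p.R307H	c.920G>A	D	B	N	N	D	25.5	0.0073	0.0071	0.0026738	rs59986512
DGR108,DGR251	chr22:40045685	p.A548T	c.1642G>A	T	B	N	N	D	6.547	0.0019	0.00087	0.00534759	rs56859827
DGR206	chr22:40056424	p.G859C	c.2575G>T	T	P	U	N	D	24.6	9.04E-06	0	0.0026738	rs747381590
DGR72	chr22:40057233	p.P905L	c.2714C>T	T	B	N	D	D	24.2	1.81E-05	8.15E-05	0.0026738	rs376992678
DGR146	chr22:40057290	p.R924K	c.2771G>A	T	B	D	D	D	17.06	2.92E-05	2.33E-05	0.0026738	rs199552874
DGR94,DGR114,DGR129	chr22:40058145	p.P991L	c.2972C>T	T	B	U	N	D	8.374	0.007	0.0052	0.00802139	rs57299573
DGR96,DGR161,DGR167,DGR226	chr22:40059828	p.Q1158H	c.3474G>C	T	D	D	D	D	23.7	0.0041	0.0046	0.01069519	rs58500586
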