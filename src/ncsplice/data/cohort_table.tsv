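patient_id	phenotype	position	gene	hgvs_c	var_type	genotype	af_1kgp	af_gnomad_eas	sift	pp2	mt	cadd
AY0815	NOA	17:2573457:G:T	PAFAH1B1	c.400G>T	Mis	Hom	NA	NA	T	B	D	25.8
AY1083	Oligozoospermia	18:23845279:G:A	TAF4B	c.489G>A	Syn	Hom	NA	0.0003	NA	NA	NA	23.7
AY1291	Oligozoospermia	X:77388835:C:G	TAF9B	c.592G>C	Mis	Hemi	NA	0.000073	NA	NA	NA	24.8
AY2043	NOA,CAH	6:32006858:C:G	CYP21A2	c.293-13C>G	Intron	Hom	0.010	0.0021	T	NA	N	14.63
AY1091	Asthenozoospermia	3:69075143:T:C	TMF1	c.2859+4A>G	Intron	Hom	NA	NA	NA	NA	NA	22.1
AY0841	MMAF	1:225446838:G:A	DNAH14	c.7022G>A	Mis	Het	0.026	0.043	D	P	D	26
AY0841	MMAF	1:225418858:G:A	DNAH14	c.6452+5G>A	Intron	Het	0.00060	0.0028	NA	NA	NA	10.43
AY0796	MMAF	3:52406083:T:A	DNAH1	c.6647T>A	Mis	Het	NA	NA	D	NA	D	25.8
AY0796	MMAF	3:52394439:A:G	DNAH1	c.4684A>G	Mis	Het	NA	NA	D	NA	D	28.3
AY1274	MMAF	10:105927385:A:T	CFAP43	c.2802T>A	Stopgain	Het	NA	NA	NA	NA	D	36
AY1274	MMAF	10:105990345:T:G	CFAP43	c.319+3A>C	Intron	Het	NA	NA	NA	NA	NA	24
AY0922	Asthenospermia	3:52420361:G:A	DNAH1	c.8811G>A	Syn	Het	NA	NA	NA	NA	NA	22.2
AY0922	Asthenospermia	3:52406083:T:A	DNAH1	c.6647T>A	Mis	Het	NA	NA	D	NA	D	25.8
AY0999	Asthenospermia	12:124272548:A:G	DNAH10	c.1436A>G	Mis	Het	NA	NA	NA	B	D	23.7
AY0999	Asthenospermia	12:124364181:G:A	DNAH10	c.8113G>A	Mis	Het	NA	NA	NA	P	D	23.7
AY1747	Asthenozoospermia	17:7722099:G:A	DNAH2	c.10670+5G>A	Intron	Hom	NA	NA	NA	NA	NA	22.7
AY0960	Asthenozoospermia	19:2098291:C:T	IZUMO4	c.479C>T	Mis	Het	NA	0.0013	D	P	N	23.7
AY0960	Asthenozoospermia	19:2097331:G:C	IZUMO4	c.298G>C	Mis	Het	NA	0.0002	D	D	D	35
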