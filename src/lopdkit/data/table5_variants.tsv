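analysis	family	gene	dbsnp	accession	func	nt_change	aa_change	maf_max	cadd_phred	sift	polyphen
Severity score > 20	F1 and F2	RILP	rs61735419	NM_031430	NSV	c.G850A	p.G284S	0.04	27.4	T	D
Severity score > 20	F1	FNIP2	rs148251675	NM_020840	NSV	c.T901C	p.S301P	0.02	23	T	T
Severity score > 20	F2	FNIP2	rs62001914	NM_020840	NSV	c.C1653A	p.S551R	0.03	25	D	T
Severity score > 20	F2	TRAPPC11	rs62617790	NM_021942	NSV	c.G2799C	p.Q933H	0.13	23	D	D
BMI	F1	PLIN2	rs759915698	NM_001122	NSV	c.C925T	p.R309C	0.00003	24	D	D
BMI	F2	PLIN2	nr	NM_001122	NSV	c.G616A	p.E206K	na	27	D	D
BMD/BF/VDD	F1	TRPV6	rs778016744	NM_018646	NSV	c.G1886A	p.R629Q	0.000008	24	T	P
BMD/BF/VDD	F1	TRPV5	nr	NM_019841	NSV	c.C1894T	p.R632W	na	33	D	D
BMD/BF/VDD	F1	KL	rs9536314	NM_004795	NSV	c.T1054G	p.F352V	0.19	27	D	D
BMD/BF/VDD	F1 and F2	IRS1	rs1801278	NM_005544	NSV	c.G2911A	p.G971R	0.08	24	T	P
BMD/BF/VDD	F2	LRP4	rs72897663	NM_002334	NSV	c.A1501C	p.N501H	0.07	21	T	T
BMD/BF/VDD	F2	LRP4	rs117936904	NM_002334	NSV	c.T5165A	p.L1722H	0.02	29	D	D
BMD/BF/VDD	F2	RUNX1	nr	NM_001754	NSV	c.G190A	p.G64S	na	23	T	P
MVP	F1	DCHS1	rs35599968	NM_003737	NSV	c.G8480C	p.R2827P	0.10	20	T	T
MVP	F1	DCHS1	rs376287018	NM_003737	NFins	c.99_100insCTG	p.G34insLG	0.10	nr	nr	nr
AR-ERT	F1	FAM26F	rs117361304	NM_001010919	splicing	c.525+2T>G	nr	0.09	25.4	nr	nr
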