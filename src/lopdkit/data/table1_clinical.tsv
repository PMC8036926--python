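ID	Family	GAA Mut	Sex	Age	AAO	MMT-MRC	6MWT	GSCG	FVC	Delta-FVC	BMI	VDD	BF	BMD-TB	BMD-FN	BMD-LSV	BAD	MVP	IgG-rhGAA	ERT-AE	DBS GAA	PPL	VMF
F1II-4	F1	p.R40X/p.N882fs	F	67	50	79	297	12	79	35	22.20	6.64	YES	-2.9	-3	-3	YES	YES	1200	NO	2.70	8	0.53
F1II-5	F1	p.R40X/p.N882fs	F	65	53	82	225	12	62	46	28.00	11.6	NO	-1.3	-1.5	-2.6	YES	YES	6400	YES	0.12	69	0.01
F1II-7	F1	p.R40X/p.N882fs	M	61	42	76	324	7	98	17	28.10	28.4	NO	-1.1	-1.5	-0.5	YES	YES	1600	NO	0.11	56	4.11
F1II-8	F1	p.R40X/p.N882fs	F	59	47	86	325	9	90	18	33.10	18.5	YES	0.5	-0.7	-0.5	YES	YES	1000	NO	0.04	80	0.45
F1II-9	F1	p.R40X/p.N882fs	M	58	38	74	254	9	83	20	21.40	12.7	NO	-0.8	-1.4	0.2	YES	YES	3200	NO	0.09	48	11.18
F1II-12	F1	p.R40X/p.N882fs	F	51	41	78	268	8	82	21	28.70	40.2	NO	1.1	2.2	0.6	YES	YES	1350	NO	0.12	16	3.59
F1II-13	F1	p.R40X/p.N882fs	M	50	36	75	254	6	105	18	20.10	41.3	NO	1.0	-0.8	-0.5	YES	NO	600	NO	0.31	59	1.30
F2II-1	F2	c.-32-13T>G/p.R375L	M	51	44	99	450	5	89	17	31.80	8.90	NO	-0.3	-0.5	0.9	NO	NO	1000	NO	0.79	52	0.05
F2II-3	F2	c.-32-13T>G/p.R375L	F	48	41	97	325	7	79	21	26.50	30.1	NO	0.4	0.1	1.3	NO	NO	1010	NO	0.13	45	0.12
F2II-4	F2	c.-32-13T>G/p.R375L	M	46	38	89	114	21	42	n.p.	39.18	8.4	NO	-0.8	-1.2	-0.5	NO	NO	850	NO	0.78	58	5.28
F2II-5	F2	c.-32-13T>G/p.R375L	F	41	29	83	10	26	36	n.p.	26.10	7.11	YES	-0.7	-2.1	1.9	NO	NO	900	NO	0.98	63	15.31
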