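ID	Sex	Age	AAO	VDD	rs2228570	rs7975232	rs731236	rs4588
F1II-4	F	67	50	6.64	CC	GT	TC	CC
F1II-5	F	65	53	11.6	CC	GG	TT	CC
F1II-7	M	61	42	28.4	CC	GG	TT	CC
F1II-8	F	59	47	18.5	CC	GT	TC	CC
F1II-9	M	58	38	12.7	TC	GT	TC	CC
F1II-12	F	51	41	40.2	TC	TT	CC	CC
F1II-13	M	50	36	41.3	CC	GT	TC	CC
F2II-1	M	51	44	8.90	CC	TT	TC	CC
F2II-3	F	48	41	30.1	CC	TT	TT	CA
F2II-4	M	46	38	8.4	CC	TT	CC	CC
F2II-5	F	41	29	7.11	CC	TT	TC	CC
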