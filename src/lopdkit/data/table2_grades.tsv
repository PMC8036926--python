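Item	F1II-4	F1II-5	F1II-7	F1II-8	F1II-9	F1II-12	F1II-13	F2II-1	F2II-3	F2II-4	F2II-5
AAO	1	1	2	2	3	2	3	2	2	3	3
MMT	3	2	3	2	3	3	3	1	1	2	2
SIXMWT	3	4	3	2	4	3	4	2	2	6	6
GSCG	2	2	1	2	2	1	1	1	1	3	4
FVC	1	2	0	0	0	0	0	0	1	4	4
DFVC	4	4	2	2	2	3	2	2	3	4	4
BMI	0	1	1	2	1	1	0	2	1	3	1
VDD	2	2	1	2	2	0	0	2	0	2	2
BMD	2	1	1	0	1	0	0	0	0	1	1
BF	1	0	0	1	0	0	0	0	0	0	1
BAD	1	1	1	1	1	1	1	0	0	0	0
MVP	1	1	1	1	1	1	1	0	0	0	0
IGG	0	1	1	0	1	0	1	0	0	0	0
ERTAE	0	1	0	0	0	0	0	0	0	0	0
SI	21	23	16	17	21	15	16	11	11	28	28
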