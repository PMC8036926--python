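patient_id	item_id	grade
F1II-4	IGG	0
F1II-8	IGG	0
F1II-12	IGG	0
F2II-1	IGG	0
F2II-3	IGG	0
F2II-4	IGG	0
F2II-5	IGG	0
F1II-9	BMI	1
F1II-13	MVP	1
F2II-5	AAO	3
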