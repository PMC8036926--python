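autophagy_lysosomal	candidate-gene pathway tags	RILP	FNIP2	TRAPPC11	PLIN2	IRS1	KL	LRP4	RUNX1
immunity	candidate-gene pathway tags	RILP	FNIP2	TRAPPC11	IRS1	KL	LRP4	RUNX1	FAM26F
bone_metabolism	candidate-gene pathway tags	TRPV5	TRPV6	IRS1	KL	LRP4	RUNX1
skeletal_muscle	candidate-gene pathway tags	TRAPPC11	PLIN2	IRS1	LRP4	RUNX1	DCHS1
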