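# input_metabolite	output_metabolite	reaction
A	B	r2
A_ext	A	r1
B	C	r3
C	E	r4
D	E	r4
D_ext	D	r6
E	F	r5
F	F_ext	r7
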