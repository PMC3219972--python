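# input_metabolite	output_metabolite	reaction
AcCoA	AcGlcD	GLCATr
AcCoA	CoA	GLCATr
AcCoA	Prod	USE
Ac_ext	AcCoA	ACS
CoA	AcCoA	ACS
DGlc	AcGlcD	GLCATr
Glc_ext	DGlc	GLCIN
Prod	P_ext	EXP
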