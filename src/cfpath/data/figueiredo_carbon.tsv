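# input_metabolite	output_metabolite	reaction
AKG	SUCCoA	AKGDH
AcCoA	Cit	CS
AcCoA	L-Mal	MALS
Cit	ICit	ACONT
D-Glc	Glc_ext	GLCex
FA_ext	AcCoA	FAO
Fum	L-Mal	FUM
G6P	D-Glc	G6PP
Glx	L-Mal	MALS
ICit	AKG	ICDHyr
ICit	Glx	ICL
ICit	SUCC	ICL
L-Mal	OAA	MDH
L-Mal	Pyr	ME1
OAA	Cit	CS
OAA	PEP	PCK1
PEP	G6P	GNEO
PEP	Pyr	PYK
Pyr	AcCoA	PDH
Pyr	OAA	PC
SUCC	Fum	SUCDi
SUCCoA	SUCC	SUCOAS
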