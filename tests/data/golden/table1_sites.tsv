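gene	codon_variant	position	codon	consequence	major_allele	maf	novel	phenotype
GDF9	R87H	chr5:41843258	cgc	missense	c	0.036	False	None reported
GDF9	E241K	chr5:41841675	gaa	missense	c	0.036	False	None reported
GDF9	V332I	chr5:41841402	gtt	missense	c	0.245	False	None reported
GDF9	V371M	chr5:41841285	gtg	missense	c	0.026	False	Fecundity
BMP15	L11ΔL	chrX:50977395	indel	inframe_indel	aagaag	0.344	False	None reported
BMP15	R67Q	chrX:50977228	cgg	missense	c	0.010	True	
BMP15	L252P	chrX:50971365	ctg	missense	a	0.083	True	
BMPR1B	M64I	chr6:29401381	atg	missense	c	0.026	True	
BMPR1B	T345N	chr6:29380795	act	missense	g	0.026	True	
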