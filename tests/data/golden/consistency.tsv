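site_id	maf	haplotype_sum	discrepancy	flagged
GDF9:R87H	0.036	0.036	0.000	False
GDF9:E241K	0.036	0.036	0.000	False
GDF9:V332I	0.245	0.245	0.000	False
GDF9:V371M	0.026	0.026	0.000	False
BMP15:L11ΔL	0.344	0.344	0.000	False
BMP15:R67Q	0.010	0.010	0.000	False
BMP15:L252P	0.083	0.083	0.000	False
BMPR1B:M64I	0.026	0.026	0.000	False
BMPR1B:T345N	0.026	0.026	0.000	False
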