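gene	variant	residues	freq
GDF9	1	R,E,V,V	0.693
GDF9	2	R,E,I,V	0.245
GDF9	3	H,K,V,V	0.036
GDF9	4	R,E,V,M	0.026
BMP15	1	L,R,L	0.656
BMP15	2	ΔL,R,L	0.250
BMP15	3	ΔL,R,P	0.083
BMP15	4	ΔL,Q,L	0.010
BMPR1B	1	M,T	0.948
BMPR1B	2	I,T	0.026
BMPR1B	3	M,N	0.026
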