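gene	variant	residues	count	denominator	frequency
GDF9	1	R,E,V,V	133	192	0.693
GDF9	2	R,E,I,V	47	192	0.245
GDF9	3	H,K,V,V	7	192	0.036
GDF9	4	R,E,V,M	5	192	0.026
BMP15	1	L,R,L	63	96	0.656
BMP15	2	ΔL,R,L	24	96	0.250
BMP15	3	ΔL,R,P	8	96	0.083
BMP15	4	ΔL,Q,L	1	96	0.010
BMPR1B	1	M,T	182	192	0.948
BMPR1B	2	I,T	5	192	0.026
BMPR1B	3	M,N	5	192	0.026
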