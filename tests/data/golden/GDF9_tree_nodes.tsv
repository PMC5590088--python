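label	residues	observed	frequency	is_root
inferred1	H,E,V,V	False	0.0	True
variant3	H,K,V,V	True	7.0	False
variant2	R,E,I,V	True	47.0	False
variant4	R,E,V,M	True	5.0	False
variant1	R,E,V,V	True	133.0	False
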