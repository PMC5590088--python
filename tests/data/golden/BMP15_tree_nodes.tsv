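label	residues	observed	frequency	is_root
variant1	L,R,L	True	63.0	True
variant4	ΔL,Q,L	True	1.0	False
variant2	ΔL,R,L	True	24.0	False
variant3	ΔL,R,P	True	8.0	False
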