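label	residues	observed	frequency	is_root
variant2	I,T	True	5.0	False
variant3	M,N	True	5.0	False
variant1	M,T	True	182.0	True
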