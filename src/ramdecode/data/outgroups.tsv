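gene	residues	note
GDF9	H,E,V,V	consensus of close relatives at the variable residues; matches the inferred interior isoform of the tree
BMP15	L,R,L	close-relative consensus equals the most frequent sheep isoform
BMPR1B	M,T	close-relative consensus equals the most frequent sheep isoform
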