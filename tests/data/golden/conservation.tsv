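gene	aa_pos	ref_residue	variant_residue	conserved_through	conserved_with_exceptions	exception_species	variant_seen_elsewhere	variant_species
GDF9	87	R	H	Artiodactyla	Artiodactyla		False	
GDF9	241	E	K	Artiodactyla	Artiodactyla		False	
GDF9	332	V	I	Artiodactyla	Artiodactyla		False	
GDF9	371	V	M	Eutheria	Theria	opossum;tasmanian_devil;wallaby	False	
BMP15	11	L	ΔL	Laurasiatheria	Laurasiatheria		False	
BMP15	67	R	Q	Laurasiatheria	Laurasiatheria		True	elephant;manatee;rabbit
BMP15	252	L	P	Laurasiatheria	Laurasiatheria		False	
BMPR1B	64	M	I	Laurasiatheria	Theria	armadillo;human;manatee	False	
BMPR1B	345	T	N	Tetrapoda	Vertebrata	coelacanth;spotted_gar;zebrafish	False	
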