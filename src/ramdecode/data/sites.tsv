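gene	label	chrom	pos_published	pos	ref	alt	aa_pos	ref_res	var_res	exon_published	domain	maf_published	flank_source	flank5	flank3
GDF9	R87H	chr5	41843258	41843258	c	t	87	R	H	1	PRO	0.037	published	ggtgggagacacagacctggtctcctttcccctctcttagaggttctgtatgatgggcacggggaaccccccaggctgcagccagatgacagagctttgc	ctacatgaagaggctctataaggcatacgctaccaaggaggggacccctaaatccaacagacgccacctctacaacactgttcggctcttcaccccctgt
GDF9	E241K	chr5	41841675	41841675	c	t	241	E	K	2	PRO	0.037	published	gaaatacaaatggatggagattgatgtgacggctcctcttgagcctctggtggcctcccacaagaggaatattcacatgtctgtaaattttacatgtgcg	aagaccagctgcagcatccttcagcgcgggacagcctgtttaacatgactcttctcgtagcgccctcactgcttttgtatctgaacgacacaagtgctca
GDF9	V332I	chr5	41841402	41841402	c	t	332	V	I	2	MAT	0.245	published	atctgcctaccccgtgggagaagaagctgctgagggtgtaagatcgtcccgtcaccgcagagaccaggagagtgccagctctgaattgaagaagcctctg	ttccagcttcagtcaatctgagtgaatacttcaaacagtttctttttccccagaatgaatgtgagctccatgactttagacttagctttagtcagctgaa
GDF9	V371M	chr5	41841285	41841285	c	t	371	V	M	2	MAT	0.026	published	tctgagtgaatacttcaaacagtttctttttccccagaatgaatgtgagctccatgactttagacttagctttagtcagctgaagtgggacaactggatt	tggccccacacaaatacaaccctcgatactgtaaaggggactgtcccagggcggtcggacatcggtatggctctccggttcacaccatggtgcagaacat
BMP15	L11ΔL	chrX	50977397	50977395	aagaag	aag	11	L	ΔL	1	PRO	0.344	published	gtaaaaggaaaggtttaaagcgttatcctttgggcttttatcagaacatgttgctgaacaccaagcttttcaagatggtcctcctgagcatccttagaatc	tggggactggtgctttttatggaacatagggtccaaatgacacaggtagggcagccctctattgcccacctgcctgaggcccctaccttgcccctgattc
BMP15	R67Q	chrX	50977228	50977228	c	t	67	R	Q	1	PRO	0.010	published	cacctgcctgaggcccctaccttgcccctgattcaggagctgctagaagaagcccctggcaagcagcagaggaagccgcgggtcttagggcatcccttac	gtatatgctggagctgtaccagcgttcagctgacgcaagtggacaccctagggaaaaccgcaccattggggccaccatggtgaggctggtgaggccgctg
BMP15	L252P	chrX	50971365	50971365	a	g	252	L	P	1	MAT	0.083	published	ttctggtggcatggcacttcatcattggacactgtcttcttgttactgtatttcaatgacactcagagtgttcagaagaccaaacctctccctaaaggcc	gaaagagtttacagaaaaagacccttctcttctcttgaggagggctcgtcaagcaggcagtattgcatcggaagttcctggcccctccagggagcatgat
BMPR1B	M64I	chr6	29401381	29401381	c	t	64	M	I	4	AR	0.026	published	acacacacacacacacacacacacacacatactttgcctgtttgatctttagcacagatggatattgtttcacgatgatagaagaagatgactctgggat	cctgtggtcacttctggatgtctaggactagaaggctcagattttcagtgtcgggtaaggaagataccttggttccactttgtaaccttttattggcaag
BMPR1B	T345N	chr6	29380795	29380795	g	t	345	T	N	9	AS-AL	0.026	synthetic
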