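chr6	29377301	29410000	BMPR1B	0	-	29377301	29410000	0	10	499,250,130,160,140,150,380,120,150,200	0,3397,9569,13539,17559,20549,23971,28579,30549,32499
chr5	41841033	41843577	GDF9	0	-	41841033	41843577	0	2	965,457	0,2087
chrX	50970937	50977507	BMP15	0	-	50970937	50977507	0	2	786,476	0,6094
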