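breed	code	n	sex
Dorper	DRP	6	M
White Dorper	WDP	4	M
Dorset	DST	11	M
Finnsheep	FIN	10	M
Katahdin	KAT	8	M
Navajo-Churro	NAV	1	M
Rambouillet	RAM	10	M
Romanov	ROM	10	M
Suffolk	SUF	9	M
Texel	TEX	10	M
Composite	CMP	17	M
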