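breed	gene	hap_a	hap_b	count
Dorper	GDF9	1	2	4
Dorper	GDF9	2	2	2
White Dorper	GDF9	1	1	2
White Dorper	GDF9	1	2	2
Dorset	GDF9	1	2	8
Dorset	GDF9	1	1	3
Finnsheep	GDF9	1	4	5
Finnsheep	GDF9	1	1	3
Finnsheep	GDF9	2	2	2
Katahdin	GDF9	1	2	4
Katahdin	GDF9	1	1	4
Navajo-Churro	GDF9	1	1	1
Rambouillet	GDF9	1	2	3
Rambouillet	GDF9	1	1	7
Romanov	GDF9	1	3	2
Romanov	GDF9	2	2	6
Romanov	GDF9	1	1	2
Suffolk	GDF9	1	2	1
Suffolk	GDF9	1	1	8
Texel	GDF9	1	3	4
Texel	GDF9	1	2	2
Texel	GDF9	1	1	4
Composite	GDF9	1	3	1
Composite	GDF9	1	2	3
Composite	GDF9	1	1	13
Dorper	BMP15	1	.	1
Dorper	BMP15	2	.	3
Dorper	BMP15	3	.	2
White Dorper	BMP15	3	.	4
Dorset	BMP15	1	.	9
Dorset	BMP15	2	.	1
Dorset	BMP15	4	.	1
Finnsheep	BMP15	1	.	7
Finnsheep	BMP15	2	.	3
Katahdin	BMP15	1	.	8
Navajo-Churro	BMP15	1	.	1
Rambouillet	BMP15	1	.	2
Rambouillet	BMP15	2	.	8
Romanov	BMP15	1	.	3
Romanov	BMP15	2	.	7
Suffolk	BMP15	1	.	9
Texel	BMP15	1	.	9
Texel	BMP15	2	.	1
Composite	BMP15	1	.	14
Composite	BMP15	2	.	1
Composite	BMP15	3	.	2
Dorper	BMPR1B	1	1	6
White Dorper	BMPR1B	1	1	4
Dorset	BMPR1B	1	1	11
Finnsheep	BMPR1B	1	3	1
Finnsheep	BMPR1B	1	1	9
Katahdin	BMPR1B	2	2	1
Katahdin	BMPR1B	1	2	1
Katahdin	BMPR1B	1	1	6
Navajo-Churro	BMPR1B	1	1	1
Rambouillet	BMPR1B	1	1	10
Romanov	BMPR1B	3	3	1
Romanov	BMPR1B	1	3	2
Romanov	BMPR1B	1	1	7
Suffolk	BMPR1B	1	1	9
Texel	BMPR1B	1	1	10
Composite	BMPR1B	1	2	2
Composite	BMPR1B	1	1	15
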