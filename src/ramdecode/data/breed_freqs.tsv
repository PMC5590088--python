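breed	gene	variant	freq
Dorper	GDF9	1	0.33
Dorper	GDF9	2	0.67
White Dorper	GDF9	1	0.75
White Dorper	GDF9	2	0.25
Dorset	GDF9	1	0.64
Dorset	GDF9	2	0.36
Finnsheep	GDF9	1	0.55
Finnsheep	GDF9	2	0.20
Finnsheep	GDF9	4	0.25
Katahdin	GDF9	1	0.75
Katahdin	GDF9	2	0.25
Navajo-Churro	GDF9	1	1.00
Rambouillet	GDF9	1	0.85
Rambouillet	GDF9	2	0.15
Romanov	GDF9	1	0.30
Romanov	GDF9	2	0.60
Romanov	GDF9	3	0.10
Suffolk	GDF9	1	0.94
Suffolk	GDF9	2	0.06
Texel	GDF9	1	0.70
Texel	GDF9	2	0.10
Texel	GDF9	3	0.20
Composite	GDF9	1	0.88
Composite	GDF9	2	0.09
Composite	GDF9	3	0.03
Dorper	BMP15	1	0.17
Dorper	BMP15	2	0.50
Dorper	BMP15	3	0.33
White Dorper	BMP15	3	1.00
Dorset	BMP15	1	0.82
Dorset	BMP15	2	0.09
Dorset	BMP15	4	0.09
Finnsheep	BMP15	1	0.70
Finnsheep	BMP15	2	0.30
Katahdin	BMP15	1	1.00
Navajo-Churro	BMP15	1	1.00
Rambouillet	BMP15	1	0.20
Rambouillet	BMP15	2	0.80
Romanov	BMP15	1	0.30
Romanov	BMP15	2	0.70
Suffolk	BMP15	1	1.00
Texel	BMP15	1	0.90
Texel	BMP15	2	0.10
Composite	BMP15	1	0.82
Composite	BMP15	2	0.06
Composite	BMP15	3	0.12
Dorper	BMPR1B	1	1.00
White Dorper	BMPR1B	1	1.00
Dorset	BMPR1B	1	1.00
Finnsheep	BMPR1B	1	0.95
Finnsheep	BMPR1B	3	0.05
Katahdin	BMPR1B	1	0.81
Katahdin	BMPR1B	2	0.19
Navajo-Churro	BMPR1B	1	1.00
Rambouillet	BMPR1B	1	1.00
Romanov	BMPR1B	1	0.80
Romanov	BMPR1B	3	0.20
Suffolk	BMPR1B	1	1.00
Texel	BMPR1B	1	1.00
Composite	BMPR1B	1	0.94
Composite	BMPR1B	2	0.06
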