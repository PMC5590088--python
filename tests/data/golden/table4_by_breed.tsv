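breed_group	n	GDF9_v1	GDF9_v2	GDF9_v3	GDF9_v4	BMP15_v1	BMP15_v2	BMP15_v3	BMP15_v4	BMPR1B_v1	BMPR1B_v2	BMPR1B_v3
Dorper	6	0.33	0.67	-	-	0.17	0.50	0.33	-	1.00	-	-
White Dorper	4	0.75	0.25	-	-	-	-	1.00	-	1.00	-	-
Dorset	11	0.64	0.36	-	-	0.82	0.09	-	0.09	1.00	-	-
Finnsheep	10	0.55	0.20	-	0.25	0.70	0.30	-	-	0.95	-	0.05
Katahdin	8	0.75	0.25	-	-	1.00	-	-	-	0.81	0.19	-
Navajo-Churro	1	1.00	-	-	-	1.00	-	-	-	1.00	-	-
Rambouillet	10	0.85	0.15	-	-	0.20	0.80	-	-	1.00	-	-
Romanov	10	0.30	0.60	0.10	-	0.30	0.70	-	-	0.80	-	0.20
Suffolk	9	0.94	0.06	-	-	1.00	-	-	-	1.00	-	-
Texel	10	0.70	0.10	0.20	-	0.90	0.10	-	-	1.00	-	-
Composite	17	0.88	0.09	0.03	-	0.82	0.06	0.12	-	0.94	0.06	-
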