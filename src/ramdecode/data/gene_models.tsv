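symbol	strand	cds_offset	protein_length	protein_id
BMPR1B	-	550	502	NP_001009431.1
GDF9	-	60	453	NP_001136360.2
BMP15	-	80	393	NP_001108239.1
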