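name	site	cut_offset
EcoRI	GAATTC	1
BamHI	GGATCC	1
HindIII	AAGCTT	1
EcoRV	GATATC	3
DraI	TTTAAA	3
SspI	AATATT	3
TaqI	TCGA	1
MseI	TTAA	1
AluI	AGCT	2
HaeIII	GGCC	2
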