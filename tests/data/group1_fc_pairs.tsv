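gene_id	transcript_fc	protein_fc
PERK	16.6	4.99
Sil1	8.58	1.8
AsnS	4.3	2.3
Ire1	2.09	1.71
Dgp-1	21.2	2.3
CG2017	2.6	1.69
Cyp6a17	117	19.03
Cyp9b2	6.96	2.28
Cyp4e3	3.22	2.97
Cyp4ad1	1.61	1.72
Ugt37A3	69.4	13.27
Ugt86Dd	3.48	3.34
GstD2	7.49	3.68
GstE8	2.7	2.08
Hsp22	29.2	28.25
Pepck2	2.63	1.65
CG34423	2.4	1.96
Lectin-galC1	3.26	9.71
BomBc3	2.56	3.92
CG11911	6.96	9.32
Uro	3.73	1.79
Ccp84Ab	1.92	1.77
CG17752	1.8	1.73
CG7632	3.57	1.95
CG43402	6.77	2.2
CG12868	2.17	2.36
CG31808	1.84	2.62
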