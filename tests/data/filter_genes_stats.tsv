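feature	comparison	cond_a	cond_b	log2fc	q
f01	A__vs__B	A	B	1.6	0.04
f02	A__vs__B	A	B	1.6	0.04
f03	A__vs__B	A	B	2.0	0.06
f04	A__vs__B	A	B	1.4	0.01
f05	A__vs__B	A	B	-1.7	0.01
f06	A__vs__B	A	B	1.5	0.05
f07	A__vs__B	A	B	1.6	0.04
f08	A__vs__B	A	B	2.0	0.20
f08	A__vs__C	A	C	1.8	0.01
f09	A__vs__B	A	B	3.0	0.001
f10	A__vs__B	A	B	1.55	0.04
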