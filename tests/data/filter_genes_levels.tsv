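feature	A	B	C
f01	12.0	1.0	0.0
f02	8.0	9.0	50.0
f03	20.0	1.0	0.0
f04	20.0	1.0	0.0
f05	2.0	11.0	0.0
f06	10.0	1.0	0.0
f07	9.99	1.0	0.0
f08	1.0	2.0	15.0
f09	0.0	0.0	0.0
f10	3.0	10.5	0.0
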