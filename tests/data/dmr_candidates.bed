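chr1	100	200	c1	0	.
chr1	150	300	c2	0	.
chr1	400	520	c3	0	.
chr1	515	640	c4	0	.
chr1	1000	1090	c5	0	.
chr1	2000	2200	c6	0	.
chr1	2100	2300	c7	0	.
chr1	3000	3180	c8	0	.
chr1	5000	5120	c9	0	.
chr1	5100	5210	c10	0	.
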