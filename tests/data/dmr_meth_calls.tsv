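chrom	pos	meth	total	sample
chr1	120	1	10	s1
chr1	180	1	10	s1
chr1	250	1	10	s1
chr1	120	1	10	s2
chr1	180	1	10	s2
chr1	250	1	10	s2
chr1	120	5	10	s3
chr1	180	5	10	s3
chr1	250	5	10	s3
chr1	120	5	10	s4
chr1	180	5	10	s4
chr1	250	5	10	s4
chr1	450	4	20	s1
chr1	450	4	20	s2
chr1	450	8	20	s3
chr1	450	8	20	s4
chr1	800	9	20	s1
chr1	1050	2	20	s1
chr1	1050	2	20	s2
chr1	1050	16	20	s3
chr1	1050	16	20	s4
chr1	2100	2	10	s1
chr1	2100	2	10	s2
chr1	2100	1	3	s3
chr1	3090	1	5	s1
chr1	3090	1	5	s2
chr1	3090	1	5	s3
chr1	3090	3	10	s4
chr1	5050	5	20	s1
chr1	5050	5	20	s2
chr1	5050	11	20	s3
chr1	5050	11	20	s4
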