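chrom	start	end	differential
chr1	100	300	True
chr1	400	640	False
chr1	1000	1090	False
chr1	5000	5210	True
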