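source_id	chrom	start	end	mapped_length	size_ratio
m01	chrB	1000	1350	350	1.0
m02	chrB	2000	2090	90	0.9
m03	chrB	3000	3100	100	1.0
m04	chrB	4000	4420	420	1.2
m05	chrB	5000	5419	419	1.197
m06	chrB	6000	6099	99	0.283
m07	chrB	7000	7500	500	1.43
m08	chrB	8000	8350	350	1.19
m09	chrB	9000	9100	100	1.2
m10	chrB	10000	10300	300	0.857
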