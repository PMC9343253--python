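m01
m03
m05
m08
m10
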