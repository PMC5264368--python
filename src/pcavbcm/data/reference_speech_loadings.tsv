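measure	F1	F2
ttr	0.082	0.973
mlu	0.803	0.488
tokens	0.904	-0.157
wpm	0.800	0.258
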