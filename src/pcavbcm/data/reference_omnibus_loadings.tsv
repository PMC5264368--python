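measure	F1	F2	F3	F4
nonword_rep_imm	0.822	0.108	0.220	0.326
nonword_rep_del	0.912	0.106	0.126	0.175
word_rep_imm	0.780	0.230	0.122	0.430
word_rep_del	0.783	0.315	0.168	0.411
digit_forward	0.841	0.239	0.058	0.198
digit_backward	0.774	0.191	0.166	0.070
nonword_min_pairs	0.584	0.203	0.683	0.167
word_min_pairs	0.586	0.421	0.505	0.237
cat_sentence	0.726	0.388	0.374	-0.050
picture_naming	0.712	0.600	0.096	0.168
boston_naming	0.659	0.629	0.013	0.209
synonym_judgement	0.353	0.714	0.347	0.244
spoken_word_pic_match	0.311	0.722	0.378	-0.190
written_word_pic_match	0.156	0.699	0.578	0.022
camel_cactus	-0.078	0.461	0.702	0.276
ravens	0.091	0.034	0.918	0.079
brixton	0.391	0.232	0.629	0.018
ttr	0.235	0.749	0.055	0.160
wpm	0.310	0.103	0.013	0.716
mlu	0.294	0.397	0.000	0.814
tokens	0.154	-0.152	0.350	0.818
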