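patient_id	age	gender	education_years	months_post_stroke	lesion_volume	aphasia_label
DBb	66	M	12	59	42687	Wernicke
ES	69	M	11	39	28146	Global
ESb	68	M	11	142	33193	Global
KW	81	M	10	24	11393	Broca
BS	59	M	11	103	27242	Broca
KL	55	M	13	31	14625	Mixed non-fluent
LM	63	M	11	13	14990	Global
DB	60	M	12	44	31644	Wernicke
PE	73	F	16	22	6959	Wernicke/conduction
KS	59	M	12	12	5822	Transcortical sensory aphasia
KK	48	M	12	33	20043	Broca
WM	77	M	11	66	33282	Mixed non-fluent
GL	47	M	12	18	26319	Broca
DCS	45	F	12	12	5273	Broca
JSa	73	M	11	190	45875	Mixed non-fluent
JSc	78	M	12	76	18459	Broca
JA	65	M	11	128	26097	Mixed non-fluent
JJ	84	M	12	25	8951	Anomia
JM	62	M	11	110	15492	Anomia
JSb	72	M	11	23	1481	Anomia
ER	64	F	14	181	26480	Mixed non-fluent
HN	81	M	10	56	25963	Anomia
BH	64	M	11	26	8795	Mixed non-fluent
EB	61	M	17	12	4806	Anomia
DM	49	M	17	42	11915	Broca
DS	72	M	11	106	11446	Transcortical motor aphasia
AG	55	M	11	131	21270	Broca
LH	65	M	11	81	10073	Anomia
JMf	70	F	11	84	8921	Anomia
AL	49	F	12	69	9767	Anomia
TJ	60	M	12	23	19975	Anomia
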