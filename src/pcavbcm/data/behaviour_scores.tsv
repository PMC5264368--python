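patient_id	nonword_rep_imm	nonword_rep_del	word_rep_imm	word_rep_del	picture_naming	boston_naming	nonword_min_pairs	word_min_pairs	spoken_word_pic_match	written_word_pic_match	cat_sentence	synonym_judgement	camel_cactus	brixton	ravens	digit_forward	digit_backward	wpm	ttr	mlu	tokens
DBb	0	0	37.5	0	0	0	22.22	52.78	57.81	31.25	12.5	48.96	53.13	38.18	30.56	25	0	63.33	53.91	60.74	23.89
ES	0	0	0	0	4.69	0	48.61	54.17	78.13	90.63	25	72.92	73.44	40	66.67	0	0	15.12	94.09	35.19	24.63
ESb	0	0	0	0	0	0	54.17	50	87.5	60.94	34.38	52.08	43.75	23.64	38.89	0	0	0	0	0	0
KW	0	0	3.75	0	1.56	0	75	65.28	95.31	92.19	84.38	82.29	89.06	50.91	80.56	50	42.86	2	86.25	12.35	2.99
BS	3.33	0	5	1.25	3.13	1.67	65.28	75	92.19	100	31.25	78.13	84.38	38.18	91.67	0	0	52.61	63.45	48.15	21.65
KL	0	0	6.25	0	4.69	1.67	75	77.78	92.19	98.44	28.13	68.75	78.13	61.82	88.89	0	0	11.87	44.72	21.16	13.44
LM	13.33	3.33	27.5	0	1.56	1.67	43.06	54.17	67.19	53.13	28.13	57.29	68.75	32.73	61.11	0	0	14.51	46	18.52	7.47
DB	70	30	85	83.75	7.81	8.33	87.5	58.33	64.06	76.56	31.25	59.38	82.81	40	86.11	37.5	14.29	17.42	38.33	65.36	89.58
PE	13.33	3.33	45	41.25	20.31	11.67	77.78	86.11	96.88	100	50	79.17	84.38	41.82	80.56	25	28.57	49.1	60.62	93.7	100
KS	73.33	80	93.75	95	31.25	13.33	94.44	95.83	71.88	67.19	84.38	84.38	68.75	52.73	86.11	100	57.14	70.53	86.6	90.53	60.47
KK	33.33	3.33	56.25	26.25	42.19	15	72.22	95.83	93.75	95.31	46.88	81.25	84.38	76.36	100	0	0	14.75	62.21	50	45.54
WM	36.67	30	55	41.25	39.06	25	47.22	63.89	92.19	75	50	61.46	51.56	43.64	61.11	37.5	28.57	5.44	65.71	22.22	10.45
GL	93.33	63.33	100	81.25	68.75	31.67	98.61	97.22	96.88	95.31	65.63	75	73.44	58.18	91.67	37.5	28.57	9.24	55.86	29.97	52.26
DCS	40	56.67	72.5	68.75	67.19	43.33	97.22	97.22	100	98.44	93.75	91.67	95.31	81.82	100	62.5	57.14	14.83	92.74	70.37	23.14
JSa	30	3.33	75	65	62.5	46.67	75	77.78	92.19	98.44	59.38	81.25	76.56	67.27	83.33	50	28.57	30.84	74.41	49.38	25.38
JSc	36.67	63.33	90	91.25	71.88	53.33	75	86.11	98.44	98.44	75	76.04	82.81	43.64	77.78	62.5	42.86	23.9	90.36	61.11	20.9
JA	36.67	40	85	78.75	79.69	63.33	90.28	95.83	100	98.44	78.13	63.54	87.5	61.82	80.56	37.5	0	46.26	74.41	60.74	25.38
JJ	36.67	23.33	82.5	73.75	85.94	63.33	51.39	80.56	98.44	98.44	56.25	93.75	53.13	43.64	41.67	62.5	42.86	41.98	85.19	82.72	40.31
JM	83.33	83.33	100	98.75	81.25	63.33	93.06	95.83	100	100	100	82.29	81.25	76.36	94.44	50	57.14	79.16	77.63	84.77	59.72
JSb	63.33	36.67	86.25	81.25	75	63.33	76.39	88.89	93.75	90.63	84.38	75	78.13	60	86.11	62.5	28.57	41.18	92	47.62	26.13
ER	53.33	36.67	70	81.25	71.88	65	81.94	88.89	95.31	93.75	56.25	84.38	90.63	41.82	38.89	25	0	46.49	82.14	95.06	47.03
HN	36.67	23.33	83.75	80	65.63	65	77.78	76.39	93.75	93.75	37.5	85.42	85.94	25.45	75	50	42.86	25.4	91.27	91.36	47.03
BH	86.67	80	100	96.25	95.31	66.67	93.06	94.44	98.44	93.75	78.13	83.33	73.44	67.27	66.67	62.5	57.14	36.77	78.68	60.49	28.37
EB	83.33	53.33	100	100	81.25	66.67	94.44	98.61	98.44	100	71.88	94.79	90.63	80	100	75	57.14	78.87	67.16	98.52	93.31
DM	60	10	73.75	68.75	75	71.67	80.56	93.06	98.44	98.44	56.25	95.83	98.44	50.91	91.67	37.5	0	23.63	84.74	50.79	28.37
DS	56.67	33.33	88.75	91.25	84.38	73.33	79.17	77.78	100	100	87.5	93.75	89.06	72.73	72.22	50	28.57	34.53	100	100	17.17
AG	73.33	83.33	77.5	87.5	87.5	78.33	100	98.61	100	100	87.5	89.58	75	56.36	75	100	100	13.06	80.5	54.81	22.4
LH	56.67	50	82.5	88.75	81.25	78.33	95.83	97.22	96.88	100	90.63	92.71	87.5	76.36	88.89	87.5	57.14	66.11	74.33	52.91	61.21
JMf	93.33	66.67	96.25	98.75	96.88	80	90.28	95.83	100	100	71.88	91.67	93.75	50.91	83.33	62.5	57.14	50.53	69	73.15	48.52
AL	90	90	100	98.75	93.75	88.33	91.67	100	100	100	84.38	93.75	79.69	60	91.67	87.5	85.71	100	86.25	87.65	44.79
TJ	93.33	83.33	98.75	92.5	95.31	95	87.5	98.61	98.44	100	68.75	88.54	70.31	52.73	50	75	28.57	38.28	76.67	81.48	38.07
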