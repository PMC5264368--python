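patient_id	F1_phon	F2_sem	F3_exe	F1_flu	F2_var	omni_F1	omni_F2	omni_F3	omni_F4
DBb	-0.332	-2.321	-2.018	0.290	-0.499	-0.775	-1.600	-2.606	1.043
ES	-1.668	-0.266	-0.331	-1.024	0.797	-1.842	0.384	-0.564	-0.256
ESb	-1.078	-0.701	-1.911	-1.360	-3.030	-0.300	-1.773	-1.290	-1.923
KW	-1.211	-0.202	0.972	-1.853	0.540	-0.832	0.387	0.700	-1.929
BS	-1.935	0.267	0.678	-0.136	-0.217	-1.952	0.249	0.604	0.120
KL	-1.810	-0.072	0.972	-1.046	-1.185	-1.391	-0.516	1.193	-1.175
LM	-0.873	-1.682	-0.765	-1.171	-1.072	-0.843	-1.445	-0.946	-0.606
DB	0.315	-2.295	0.594	1.151	-2.058	-0.149	-2.555	0.658	1.491
PE	-1.067	0.358	0.459	1.961	-0.980	-1.426	-0.090	0.706	1.723
KS	1.726	-2.395	0.718	1.209	0.616	1.274	-1.524	-0.015	1.274
KK	-1.207	0.161	1.319	-0.164	-0.642	-1.129	-0.158	1.504	-0.149
WM	-0.036	-0.525	-1.344	-1.364	-0.297	0.363	-0.567	-1.198	-1.458
GL	0.618	-0.361	0.583	-0.284	-1.181	0.971	-1.148	1.107	-0.715
DCS	0.208	0.045	1.680	-0.642	1.080	0.346	0.564	1.351	-0.819
JSa	-0.321	0.309	0.233	-0.453	0.148	-0.240	0.358	0.221	-0.398
JSc	0.416	0.356	-0.256	-0.643	0.947	0.461	0.657	-0.344	-0.500
JA	-0.124	0.593	0.308	-0.099	0.279	0.009	0.377	0.417	-0.170
JJ	0.236	1.429	-2.197	0.307	0.706	0.131	1.420	-2.027	0.348
JM	0.993	-0.053	0.863	1.328	0.227	0.998	-0.210	0.805	0.683
JSb	0.472	0.006	0.120	-0.456	0.854	0.537	0.269	0.003	-0.409
ER	-0.241	1.337	-1.092	0.677	0.612	-0.622	1.273	-0.957	1.189
HN	-0.089	0.712	-0.692	0.253	0.909	-0.534	1.048	-0.754	0.927
BH	1.204	0.216	-0.296	-0.214	0.392	1.422	0.090	-0.198	-0.522
EB	0.760	0.174	1.150	2.256	-0.526	0.451	-0.204	1.215	1.739
DM	-0.607	1.269	0.420	-0.566	0.525	-0.727	1.239	0.551	-0.013
DS	0.128	1.045	0.041	-0.199	1.760	-0.051	1.653	-0.282	0.129
AG	1.419	0.210	-0.064	-0.759	0.451	1.810	0.244	-0.018	-1.321
LH	0.704	0.354	0.807	0.830	-0.240	0.765	0.101	0.885	0.234
JMf	0.811	0.737	0.110	0.624	-0.131	0.755	0.391	0.294	0.467
AL	1.446	0.262	0.228	1.285	0.842	1.353	0.365	0.000	0.834
TJ	1.141	1.029	-1.289	0.265	0.373	1.165	0.718	-1.013	0.161
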