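population	RH	AGB	LA	SLA	LDMC	FvFm	PI	SPS	SPI	iFD_CV
KW	52.1	0.91	891	16.4	270.5	NA	NA	260.3	2.95	0.173
Bo	12.3	0.28	237	17.1	269.9	0.841	9.45	230.5	3.35	0.228
Ha	23.7	0.96	641	15.8	272.4	0.847	11.75	255.3	2.64	0.205
Wo	34.4	2.02	1071	17.0	255.7	0.841	7.91	239.9	2.96	0.210
Ba	25.8	0.68	359	16.9	274.5	0.838	10.16	254.4	2.92	0.196
St	23.8	0.39	296	17.3	292.2	0.830	7.80	259.6	2.88	0.265
Sa	31.4	0.96	922	15.6	277.8	0.839	9.91	237.3	2.73	0.242
If	39.0	1.14	684	15.0	289.9	0.839	7.21	251.5	2.59	0.184
Ni	53.6	1.57	1332	14.0	268.6	0.841	9.21	275.8	2.83	0.204
Di	47.8	1.22	430	16.1	268.8	0.825	6.32	282.0	3.52	0.202
Er	42.2	1.28	743	16.7	264.9	0.846	8.50	243.7	2.59	0.224
Gr	27.5	0.86	855	17.7	262.5	0.848	10.20	266.3	2.53	0.149
Eh	52.9	1.10	1260	16.5	251.1	0.841	10.40	266.8	2.53	0.153
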