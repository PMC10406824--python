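population	altitude	T_a	P_a	slope	slope_exposure	LAI	crop_height	soil_depth	CEC_pot	pH	N	P	K	wL	wK	wF	wT	wR	wN	S	E	cover_herb	bare_ground	HD
KW	1057	5.7	1045	2.0	NW	5.0	NA	16.8	12.9	6.1	0.57	0.7	3.6	6.7	3.6	5.5	4.2	6.8	4.1	31	0.82	97	1	0.143
Bo	180	8.7	511	3.0	NE	1.2	11	10.9	15.6	5.6	0.36	0.8	5.2	7.9	3.3	3.3	5.5	7.7	2.8	14	0.79	91	8	0.303
Ha	233	8.4	548	12.7	W	2.1	23	14.6	16.0	6.7	0.41	1.3	20.0	7.4	4.5	3.8	5.6	7.5	3.3	20	0.73	94	5	0.235
Wo	298	7.8	628	6.6	W	2.4	59	13.6	15.9	7.7	0.42	1.2	23.8	7.6	3.3	3.4	5.4	7.9	3.1	28	0.73	89	5	0.257
Ba	260	8.2	565	18.3	W	1.9	56	21.5	14.8	5.4	0.61	0.9	8.6	7.6	3.9	3.1	5.5	7.9	2.6	19	0.68	81	10	0.244
St	265	8.2	567	9.1	NE	1.2	46	19.0	16.3	7.6	0.58	1.4	7.0	7.7	3.6	3.1	5.5	7.9	2.7	24	0.66	95	3	0.357
Sa	332	8.1	598	5.5	NW	1.9	39	16.6	15.7	8.0	0.59	2.0	12.4	7.5	3.8	3.5	5.3	7.6	3.0	20	0.60	86	8	0.325
If	358	7.7	709	7.2	SW	2.4	51	17.7	16.8	7.9	0.37	0.6	16.0	7.7	3.0	3.3	5.3	7.8	2.9	29	0.65	94	5	0.150
Ni	366	7.7	588	16.5	N	4.1	36	15.8	17.5	7.8	0.61	1.7	25.2	7.8	3.4	3.2	5.3	7.8	2.8	24	0.68	98	2	0.169
Di	232	8.3	535	7.9	NW	4.4	83	21.0	16.6	7.5	0.41	1.0	14.6	7.4	4.0	3.8	5.5	7.5	4.6	33	0.83	99	1	0.295
Er	546	6.9	767	10.2	W	5.8	57	9.6	16.3	7.7	0.72	2.6	24.4	7.7	3.6	3.3	5.4	7.8	2.7	29	0.80	97	2	0.346
Gr	540	6.7	734	16.1	S	2.4	23	11.0	14.8	7.3	0.83	0.9	6.0	7.6	3.4	3.5	5.3	7.5	3.1	30	0.74	96	3	0.151
Eh	499	7.4	661	4.9	N	3.5	45	10.9	16.7	7.8	0.75	2.4	28.0	6.9	4.2	4.0	5.3	7.5	4.1	19	0.69	76	0	0.193
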