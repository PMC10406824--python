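population	N	n	N_A	P_Ap	H_o	H_e	I	F_IS	G_ST
KW	350	20	52	5.770	0.533	0.597	1.251	0.107	0.067
Bo	2300	20	63	1.590	0.604	0.612	1.343	0.013	0.054
Ha	1100	20	71	5.630	0.594	0.630	1.450	0.057	0.042
Wo	5400	20	68	4.410	0.654	0.654	1.460	0.000	0.035
Ba	260	19	53	0.000	0.560	0.666	1.384	0.159	0.049
St	10400	19	63	1.590	0.662	0.686	1.472	0.035	0.060
Sa	640	20	56	3.570	0.622	0.637	1.347	0.024	0.056
If	8100	18	59	1.690	0.667	0.678	1.465	0.016	0.032
Ni	9300	20	64	4.690	0.630	0.661	1.473	0.047	0.041
Di	100	20	56	0.000	0.607	0.647	1.369	0.062	0.042
Er	20900	20	59	5.080	0.690	0.658	1.419	-0.049	0.042
Gr	150	19	49	0.000	0.531	0.570	1.185	0.068	0.059
Eh	50	20	52	3.850	0.575	0.595	1.241	0.034	0.056
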