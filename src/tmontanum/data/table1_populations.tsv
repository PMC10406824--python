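population	locality	date	latitude	longitude	habitat_area_m2	abundance_per_m2	population_size	size_class
KW	Riezlern	17.07.2015	47.361036	10.173825	285	1.23	350	small
Bo	Bottendorf	22.05.2016	51.316042	11.396525	2101	1.12	2300	large
Ha	Hardisleben	25.05.2016	51.162917	11.446789	1249	0.92	1100	small
Wo	Jena-Wogau	29.05.2016	50.924306	11.665083	959	5.63	5400	large
Ba	Bad Frankenhausen	31.05.2016	51.367267	11.103056	197	1.34	260	small
St	Steinthaleben	05.06.2016	51.409550	11.004850	1394	7.45	10400	large
Sa	Saalfeld	08.06.2016	50.631003	11.383729	452	1.41	640	small
If	Ifta	12.06.2016	51.086633	10.148017	3981	2.03	8100	large
Ni	Niederwillingen	15.06.2016	50.776294	11.027711	951	9.73	9300	large
Di	Dielsdorf	19.06.2016	51.0952330	11.188406	23	4.06	100	small
Er	Erbenhausen	23.06.2016	50.565556	10.157383	4627	4.52	20900	large
Gr	Grossneundorf	28.06.2016	50.532456	11.294961	174	0.87	150	small
Eh	Ehrenberg	29.06.2016	50.478583	10.665786	20	2.26	50	small
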