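chrom	pos	rsid	a1	beta_pat	se_pat	p_pat	beta_mat	se_mat	p_mat	p_diff	trait	locus	scan	poe_class
11	1914139	rs576603	T	-0.027	0.004	8.53e-11	0.005	0.004	2.03e-1	3.86e-8	Standing height	H19/IGF2	I	P
11	2813322	rs143840904	T	-0.023	0.015	1.37e-1	-0.183	0.016	9.13e-32	5.21e-13	Standing height	KCNQ1	IAG	M
11	2040272	rs77708343	G	-0.055	0.011	2.21e-7	0.034	0.010	1.07e-3	2.18e-9	Standing height	H19/IGF2	I	B
11	2040272	rs77708343	G	-0.048	0.011	1.25e-5	0.035	0.011	1.33e-3	7.53e-8	Basal metabolic rate	H19/IGF2	I	B
11	2040272	rs77708343	G	-0.052	0.011	1.28e-6	0.033	0.011	2.06e-3	1.80e-8	Leg fat-free mass	H19/IGF2	I	B
11	2040272	rs77708343	G	-0.044	0.010	3.08e-5	0.033	0.010	1.23e-3	1.63e-7	Whole-body water mass	H19/IGF2	I	B
11	2041348	rs78507815	T	-0.031	0.009	7.03e-4	0.033	0.009	1.86e-4	3.61e-7	Trunk fat-free mass	H19/IGF2	I	B
11	1920285	rs4264135	G	-0.033	0.006	1.83e-7	0.014	0.006	3.31e-2	2.22e-7	Urate level	H19/IGF2	I	P
11	1998031	rs170102	A	-0.041	0.006	5.96e-11	0.026	0.006	3.19e-5	5.98e-14	Cystatin C level	H19/IGF2	IG	B
11	2003944	rs217215	G	0.030	0.006	2.53e-7	-0.024	0.006	2.68e-5	4.94e-11	Creatinine level	H19/IGF2	IG	B
11	1703564	rs4417225	T	0.029	0.008	9.26e-5	-0.028	0.008	2.04e-4	7.40e-8	Glucose level	H19/IGF2	I	B
11	1702929	rs10838787	A	0.136	0.027	3.88e-7	-0.091	0.027	7.55e-4	1.87e-9	Type 2 diabetes	H19/IGF2	I	B
11	1702929	rs10838787	A	0.050	0.007	2.34e-14	-0.028	0.007	1.80e-5	2.77e-17	HbA1c level	H19/IGF2	IG	B
11	2858295	rs2299620	T	-0.011	0.018	5.22e-1	-0.129	0.017	1.50e-13	2.23e-6	HbA1c level	KCNQ1	IA	M
7	130009312	rs10239342	G	0.022	0.007	1.36e-3	-0.024	0.007	4.15e-4	1.87e-6	SHBG level	KLF14/MEST	I	B
7	130016470	rs62471721	A	-0.023	0.007	9.70e-4	0.033	0.007	1.57e-6	6.51e-9	Triglyceride level	KLF14/MEST	I	B
7	130017940	rs4731690	G	0.019	0.006	1.97e-3	-0.022	0.006	2.76e-4	1.92e-6	HDL-C level	MEST	I	B
7	130463192	rs6467315	G	0.001	0.006	9.02e-1	-0.042	0.006	5.81e-11	2.20e-6	Hip circumference	KLF14	I	M
7	130400698	rs3847104	A	-0.016	0.010	1.01e-1	0.056	0.010	1.94e-8	3.81e-7	Hip circumference	KLF14	I	M
20	57216538	rs80116540	G	0.035	0.010	4.38e-4	-0.043	0.010	2.04e-5	3.39e-8	Arm fat percentage	GNAS	I	B
20	57216538	rs80116540	G	0.037	0.010	2.65e-4	-0.037	0.010	2.27e-4	2.06e-7	Body fat percentage	GNAS	I	B
20	57226079	rs6026426	G	0.045	0.012	3.08e-4	-0.040	0.012	1.37e-3	1.29e-6	Trunk fat percentage	GNAS	I	B
20	57484934	rs3730173	T	0.036	0.010	3.18e-4	-0.035	0.010	3.95e-4	5.32e-7	Leg fat percentage	GNAS	I	B
6	144274210	rs12528876	C	-0.036	0.009	2.58e-5	0.021	0.009	1.60e-2	2.96e-6	IGF1 level	PLAGL1	I	B
16	3412861	rs7188903	G	-0.012	0.007	1.03e-1	0.041	0.007	5.35e-8	6.14e-7	IGF1 level	ZNF597/NAA60	I	M
15	25983333	rs146982369	G	0.101	0.032	1.88e-3	-0.106	0.032	9.99e-4	2.59e-6	Total protein level	ATP10A	I	B
14	101185187	rs59228823	C	-0.010	0.008	2.04e-1	-0.092	0.008	3.87e-34	1.92e-14	Platelet count	MEG3	IAG	M
3	169482335	rs2293607	C	-0.122	0.008	2.26e-55	-0.068	0.008	5.36e-18	5.70e-7	Telomere length ratio	TERC	A	PA
4	164012901	rs11100479	T	0.079	0.008	1.82e-22	0.022	0.008	6.61e-3	6.25e-7	Telomere length ratio	NAF1	A	P
5	1285974	rs7705526	A	0.038	0.007	2.09e-7	0.106	0.007	1.27e-47	5.82e-11	Telomere length ratio	TERT	AG	M
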