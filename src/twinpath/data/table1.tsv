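region_number	region	r_mz	p_mz	r_dz	p_dz	rmz_minus_rdz	two_rdz_minus_rmz	initial_model	best_model	delta_aic	p_vs_e	cluster
1	SFG_L_7_1	0.28	0.001	0.11	0.194	0.17	-0.06	ADE	DE	7.63	0.002	5
2	MFG_L_7_2	0.25	0.004	0.41	0.001	-0.16	-	ACE	CE	13.86	***	-
3	IFG_L_6_1	0.18	0.029	0.21	0.051	-0.03	-	ACE	CE	4.03	0.014	-
4	IFG_L_6_2	0.34	0.000	0.15	0.134	0.19	-0.04	ADE	DE	12.90	***	5
5	IFG_L_6_3	0.23	0.007	0.06	0.325	0.17	-0.11	ADE	DE	4.43	0.011	5
6	IFG_L_6_4	0.27	0.002	0.10	0.227	0.17	-0.07	ADE	DE	7.19	0.002	5
7	IFG_L_6_5	0.26	0.002	0.18	0.084	0.08	0.10	ACE	E	-	-	-
8	ORG_L_6_2	0.26	0.003	0.23	0.040	0.03	0.20	ACE	CE	8.59	0.001	-
9	ORG_L_6_6	0.26	0.003	0.26	0.021	0.00	-	ACE	CE	9.60	***	-
10	PrG_L_6_1	0.09	0.163	0.04	0.370	0.05	-0.01	ADE	E	-	-	-
11	PrG_L_6_3	0.16	0.047	0.30	0.010	-0.14	-	ACE	CE	5.58	0.006	-
12	STG_L_6_1	0.21	0.013	0.17	0.099	0.04	0.13	ACE	CE	5.15	0.008	-
13	STG_L_6_2	0.30	0.001	-0.03	0.586	0.33	-0.36	ADE	DE	7.82	0.002	4
14	STG_R_6_2	0.26	0.002	-0.13	0.833	0.39	-0.52	ADE	DE	4.68	0.01	4
15	STG_L_6_3	0.23	0.008	-0.09	0.752	0.32	-0.41	ADE	DE	3.14	0.023	4
16	STG_R_6_3	0.32	0.000	-0.09	0.747	0.41	-0.50	ADE	DE	9.39	***	4
17	STG_L_6_4	0.27	0.002	0.06	0.335	0.21	-0.15	ADE	DE	6.74	0.003	2
18	STG_R_6_4	0.30	0.001	-0.13	0.842	0.43	-0.56	ADE	DE	7.04	0.003	4
19	STG_L_6_5	0.30	0.001	0.10	0.229	0.20	-0.10	ADE	AE	8.64	0.001	1
20	STG_R_6_5	0.33	0.000	0.02	0.444	0.31	-0.29	ADE	DE	11.10	***	3
21	STG_L_6_6	0.32	0.000	0.14	0.145	0.18	-0.04	ADE	AE	11.14	***	2
22	STG_R_6_6	0.41	0.000	0.00	0.513	0.41	-0.41	ADE	DE	17.21	***	3
23	MTG_L_4_2	0.37	0.000	0.09	0.252	0.28	-0.19	ADE	DE	15.37	***	1
24	MTG_R_4_2	0.37	0.000	0.09	0.243	0.28	-0.19	ADE	DE	15.82	***	1
25	MTG_L_4_4	0.41	0.000	0.15	0.130	0.26	-0.11	ADE	DE	19.96	***	1
26	MTG_R_4_4	0.38	0.000	0.01	0.475	0.37	-0.36	ADE	DE	14.64	***	3
27	ITG_L_7_3	0.36	0.000	0.04	0.383	0.32	-0.28	ADE	DE	13.22	***	1
28	FuG_L_3_1	0.06	0.247	0.33	0.005	-0.27	-	ACE	AE	0.15	0.14	-
29	pSTS_L_2_1	0.38	0.000	-0.03	0.588	0.41	-0.44	ADE	DE	14.72	***	2
30	pSTS_R_2_1	0.31	0.000	-0.10	0.772	0.41	-0.51	ADE	DE	7.49	0.002	3
31	pSTS_L_2_2	0.30	0.001	-0.13	0.832	0.43	-0.56	ADE	DE	6.83	0.003	2
32	IPL_L_6_5	0.26	0.002	0.12	0.180	0.14	-0.02	ADE	DE	6.95	0.003	5
33	IPL_L_6_6	0.15	0.058	-0.03	0.600	0.18	-0.21	ADE	DE	0.11	0.15	-
34	PoG_L_4_2	0.14	0.062	0.05	0.343	0.09	-0.04	ADE	DE	0.35	0.13	-
35	PoG_R_4_2	0.08	0.201	0.00	0.508	0.08	-0.08	ADE	E	-	-	-
36	Hipp_L_2_1	0.00	0.486	0.09	0.243	-0.09	-	ACE	E	-	-	-
37	BG_L_6_1	0.04	0.341	-0.04	0.611	0.08	-0.12	ADE	E	-	-	-
38	BG_L_6_3	-0.08	0.806	-0.13	0.832	0.05	-	ACE	E	-	-	-
39	BG_L_6_5	0.28	0.001	0.10	0.215	0.18	-0.08	ADE	AE	8.10	0.001	6
40	BG_R_6_5	0.24	0.005	-0.14	0.847	0.38	-0.52	ADE	DE	3.79	0.016	6
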