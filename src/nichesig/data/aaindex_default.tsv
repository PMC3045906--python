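index_code	description	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
BURA740102	Normalized frequency of extended structure (Burgess et al., 1974)	0.288	0.533	0.271	0.262	0.318	0.312	0.200	0.411	0.265	0.400	0.375	0.229	0.340	0.327	0.362	0.354	0.388	0.495	0.231	0.429
CHOP780101	Normalized frequency of beta-turn (Chou-Fasman, 1978a)	0.66	1.19	1.46	0.74	0.60	1.56	0.95	0.47	1.01	0.59	0.60	1.56	1.52	0.98	0.95	1.43	0.96	0.50	0.96	1.14
ROBB760113	Information measure for loop (Robson-Suzuki, 1976)	-5.1	3.8	3.1	-5.2	-2.4	5.6	-0.9	-4.5	1.0	-5.4	-5.3	4.7	3.5	0.2	2.6	3.2	0.0	-6.3	2.9	3.2
CHAM830101	The Chou-Fasman parameter of the coil conformation (Charton-Charton, 1983)	0.71	1.19	1.21	0.84	0.71	1.52	1.07	0.66	0.99	0.69	0.59	1.37	1.61	0.87	1.06	1.34	1.08	0.63	0.76	1.07
HOPT810101	Hydrophilicity value (Hopp-Woods, 1981)	-0.5	-1.0	3.0	3.0	-2.5	0.0	-0.5	-1.8	3.0	-1.8	-1.3	0.2	0.0	0.2	3.0	0.3	-0.4	-1.5	-3.4	-2.3
GRAR740102	Polarity (Grantham, 1974)	8.1	5.5	13.0	12.3	5.2	9.0	10.4	5.2	11.3	4.9	5.7	11.6	8.0	10.5	10.5	9.2	8.6	5.9	5.4	6.2
KYTJ820101	Hydropathy index (Kyte-Doolittle, 1982)	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
EISD840101	Consensus normalized hydrophobicity scale (Eisenberg, 1984)	0.25	0.04	-0.72	-0.62	0.61	0.16	-0.40	0.73	-1.10	0.53	0.26	-0.64	-0.07	-0.69	-1.76	-0.26	-0.18	0.54	0.37	0.02
FAUJ880103	Normalized van der Waals volume (Fauchere et al., 1988)	1.00	2.43	2.78	3.78	5.89	0.00	4.66	4.00	4.77	4.00	4.43	2.95	2.72	3.95	6.13	1.60	2.60	3.00	8.08	6.47
GRAR740103	Volume (Grantham, 1974)	31.0	55.0	54.0	83.0	132.0	3.0	96.0	111.0	119.0	111.0	105.0	56.0	32.5	85.0	124.0	32.0	61.0	84.0	170.0	136.0
ZIMJ680104	Isoelectric point (Zimmerman et al., 1968)	6.00	5.05	2.77	3.22	5.48	5.97	7.59	6.02	9.74	5.98	5.74	5.41	6.30	5.65	10.76	5.68	5.66	5.96	5.89	5.66
BHAR880101	Average flexibility indices (Bhaskaran-Ponnuswamy, 1988)	0.357	0.346	0.511	0.497	0.314	0.544	0.323	0.462	0.466	0.365	0.295	0.463	0.509	0.493	0.529	0.507	0.444	0.386	0.305	0.420
CHOP780201	Normalized frequency of alpha-helix (Chou-Fasman, 1978b)	1.42	0.70	1.01	1.51	1.13	0.57	1.00	1.08	1.16	1.21	1.45	0.67	0.57	1.11	0.98	0.77	0.83	1.06	1.08	0.69
CHOP780202	Normalized frequency of beta-sheet (Chou-Fasman, 1978b)	0.83	1.19	0.54	0.37	1.38	0.75	0.87	1.60	0.74	1.30	1.05	0.89	0.55	1.10	0.93	0.75	1.19	1.70	1.37	1.47
CHAM820101	Polarizability parameter (Charton-Charton, 1982)	0.046	0.128	0.105	0.151	0.290	0.000	0.230	0.186	0.219	0.186	0.221	0.134	0.131	0.180	0.291	0.062	0.108	0.140	0.409	0.298
CHAM820102	Free energy of solution in water, kcal/mole (Charton-Charton, 1982)	-0.368	4.530	2.060	1.770	1.060	-0.525	0.000	0.791	0.000	1.070	0.656	0.000	-2.240	0.731	-1.030	-0.524	0.000	0.401	1.600	4.910
JANJ780101	Average accessible surface area (Janin et al., 1978)	27.8	15.5	60.6	68.2	25.5	24.5	50.7	22.8	103.0	27.6	33.5	60.1	51.5	68.7	94.7	42.0	45.0	23.7	34.7	55.2
LEVM760101	Hydrophobic parameter (Levitt, 1976)	-0.5	-1.0	2.5	2.5	-2.5	0.0	-0.5	-1.8	3.0	-1.8	-1.3	0.2	-1.4	0.2	3.0	0.3	-0.4	-1.5	-3.4	-2.3
BIGC670101	Residue volume (Bigelow, 1967)	52.6	68.3	68.4	84.7	113.9	36.3	91.9	102.0	105.1	102.0	97.7	75.7	73.6	89.7	109.1	54.9	71.2	85.1	135.4	116.2
BULH740101	Transfer free energy to surface (Bull-Breese, 1974)	-0.20	-0.45	-0.20	-0.30	-2.33	0.00	-0.12	-2.26	-0.35	-2.46	-1.47	0.08	-0.98	0.16	-0.12	-0.39	-0.52	-1.56	-2.01	-2.24
BULH740102	Apparent partial specific volume (Bull-Breese, 1974)	0.691	0.624	0.558	0.632	0.756	0.592	0.646	0.809	0.767	0.842	0.709	0.596	0.730	0.649	0.728	0.594	0.655	0.777	0.743	0.743
CHOC760101	Residue accessible surface area in tripeptide (Chothia, 1976)	115	135	150	190	210	75	195	175	200	170	185	160	145	180	225	115	140	155	255	230
CHOC760102	Residue accessible surface area in folded protein (Chothia, 1976)	25	19	50	49	24	23	43	18	97	23	31	63	50	71	90	44	47	18	32	60
DAYM780101	Amino acid composition (Dayhoff et al., 1978a)	8.6	2.9	5.5	6.0	3.6	8.4	2.0	4.5	6.6	7.4	1.7	4.3	5.2	3.9	4.9	7.0	6.1	6.6	1.3	3.4
FASG760101	Molecular weight (Fasman, 1976)	89.09	121.15	133.10	147.13	165.19	75.07	155.16	131.17	146.19	131.17	149.21	132.12	115.13	146.15	174.20	105.09	119.12	117.15	204.24	181.19
FAUJ880109	Number of hydrogen bond donors (Fauchere et al., 1988)	0	0	1	1	0	0	1	0	2	0	0	2	0	2	4	1	1	0	1	1
FAUJ880110	Number of full nonbonding orbitals (Fauchere et al., 1988)	0	0	4	4	0	0	1	0	1	0	0	3	0	3	3	2	2	0	0	2
FAUJ880111	Positive charge (Fauchere et al., 1988)	0	0	0	0	0	0	1	0	1	0	0	0	0	0	1	0	0	0	0	0
FAUJ880112	Negative charge (Fauchere et al., 1988)	0	0	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
GOLD730101	Hydrophobicity factor (Goldsack-Chalifoux, 1973)	0.75	1.00	0.00	0.00	2.65	0.00	0.00	2.95	1.50	2.40	1.30	0.69	2.60	0.59	0.75	0.00	0.45	1.70	3.00	2.85
HUTJ700102	Absolute entropy (Hutchens, 1970)	30.88	53.83	40.66	44.98	51.06	24.74	65.99	49.71	63.21	50.62	55.32	41.70	39.21	46.62	68.43	35.65	36.50	42.75	60.00	51.15
HUTJ700103	Entropy of formation (Hutchens, 1970)	154.33	219.79	194.91	223.16	204.74	127.90	242.54	233.21	300.46	232.30	202.65	207.90	179.93	235.51	341.01	174.06	205.80	207.60	237.01	229.15
ISOY800101	Normalized relative frequency of alpha-helix (Isogai et al., 1980)	1.53	0.89	1.00	1.63	1.22	0.44	1.03	1.07	1.26	1.32	1.66	0.60	0.25	1.27	1.17	0.65	0.86	0.93	1.05	0.70
JOND750101	Hydrophobicity (Jones, 1975)	0.87	1.52	0.66	0.67	2.87	0.10	0.87	3.15	1.64	2.17	1.67	0.09	2.77	0.00	0.85	0.07	0.07	1.87	3.77	2.67
KLEP840101	Net charge (Klein et al., 1984)	0	0	-1	-1	0	0	0	0	1	0	0	0	0	0	1	0	0	0	0	0
KRIW790101	Side chain interaction parameter (Krigbaum-Komoriya, 1979)	4.32	1.73	6.04	6.17	2.59	6.09	5.66	2.31	7.92	3.93	2.44	6.24	7.19	6.13	6.55	5.37	5.16	3.31	2.78	3.58
LIFS790101	Conformational preference for all beta-strands (Lifson-Sander, 1979)	0.92	1.16	0.48	0.61	1.25	0.61	0.93	1.81	0.70	1.30	1.19	0.60	0.40	0.95	0.93	0.82	1.12	1.81	1.54	1.53
MANP780101	Average surrounding hydrophobicity (Manavalan-Ponnuswamy, 1978)	12.97	14.63	10.85	11.89	14.00	12.43	12.16	15.67	11.36	14.90	14.39	11.42	11.37	11.76	11.72	11.23	11.69	15.71	13.93	13.42
MEEJ800101	Retention coefficient in HPLC, pH7.4 (Meek, 1980)	0.5	-6.8	-8.2	-16.9	13.2	0.0	-3.5	13.9	0.1	8.8	4.8	0.8	6.1	-4.8	0.8	1.2	2.7	2.7	14.9	6.1
NAKH900101	AA composition of total proteins (Nakashima et al., 1990)	7.99	1.81	5.14	6.10	3.83	6.91	2.17	5.48	6.01	9.16	2.50	4.33	4.95	3.98	5.86	6.84	5.77	6.65	1.34	3.15
OOBM770101	Average non-bonded energy per atom (Oobatake-Ooi, 1977)	-1.895	-2.035	-1.518	-1.535	-1.864	-1.898	-1.755	-1.951	-1.374	-1.966	-1.963	-1.560	-1.699	-1.521	-1.475	-1.753	-1.767	-1.981	-1.869	-1.686
PONP800101	Surrounding hydrophobicity in folded form (Ponnuswamy et al., 1980)	12.28	14.93	10.97	11.19	13.43	12.01	12.84	14.77	10.80	14.10	14.33	11.00	11.19	11.28	11.49	11.26	11.65	15.07	12.95	13.29
RADA880108	Mean polarity (Radzicka-Wolfenden, 1988)	-0.06	1.36	-0.80	-0.77	1.27	-0.41	0.49	1.31	-1.18	1.21	1.27	-0.48	0.00	-0.73	-0.84	-0.50	-0.27	1.09	0.88	0.33
ROBB760101	Information measure for alpha-helix (Robson-Suzuki, 1976)	6.5	-1.3	0.5	7.8	1.6	-8.6	1.2	0.6	2.3	3.2	5.3	-5.1	-7.7	1.0	-0.9	-3.9	-2.6	1.4	1.2	-4.5
ROSG850101	Mean area buried on transfer (Rose et al., 1985)	86.6	132.3	97.8	113.9	194.1	62.9	155.8	158.0	115.5	164.1	172.9	103.3	92.9	119.2	162.2	85.6	106.5	141.0	224.6	177.7
WOEC730101	Polar requirement (Woese, 1973)	7.0	5.5	13.0	12.5	5.0	7.9	8.4	4.9	10.1	4.9	5.3	10.0	6.6	8.6	9.1	7.5	6.6	5.6	5.3	5.7
ZIMJ680101	Hydrophobicity (Zimmerman et al., 1968)	0.83	1.48	0.64	0.65	2.75	0.10	1.10	3.07	1.60	2.52	1.40	0.09	2.70	0.00	0.83	0.14	0.54	1.79	0.31	2.97
ZIMJ680103	Polarity (Zimmerman et al., 1968)	0.00	1.48	49.70	49.90	0.35	0.00	51.60	0.13	49.50	0.13	1.43	3.38	1.58	3.53	52.00	1.67	1.66	0.13	2.10	1.61
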