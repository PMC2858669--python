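name	category	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
kyte_doolittle	hydrophobicity	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
hopp_woods	hydrophobicity	-0.5	-1.0	3.0	3.0	-2.5	0.0	-0.5	-1.8	3.0	-1.8	-1.3	0.2	0.0	0.2	3.0	0.3	-0.4	-1.5	-3.4	-2.3
eisenberg_consensus	hydrophobicity	0.62	0.29	-0.90	-0.74	1.19	0.48	-0.40	1.38	-1.50	1.06	0.64	-0.78	0.12	-0.85	-2.53	-0.18	-0.05	1.08	0.81	0.26
fauchere_pliska	hydrophobicity	0.31	1.54	-0.77	-0.64	1.79	0.00	0.13	1.80	-0.99	1.70	1.23	-0.60	0.72	-0.22	-1.01	-0.04	0.26	1.22	2.25	0.96
janin	hydrophobicity	0.3	0.9	-0.6	-0.7	0.5	0.3	-0.1	0.7	-1.8	0.5	0.4	-0.5	-0.3	-0.7	-1.4	-0.1	-0.2	0.6	0.3	-0.4
engelman_ges	hydrophobicity	1.6	2.0	-9.2	-8.2	3.7	1.0	-3.0	3.1	-8.8	2.8	3.4	-4.8	-0.2	-4.1	-12.3	0.6	1.2	2.6	1.9	-0.7
wimley_white_interface	hydrophobicity	0.17	-0.24	1.23	2.02	-1.13	0.01	0.17	-0.31	0.99	-0.56	-0.23	0.42	0.45	0.58	0.81	0.13	0.14	0.07	-1.85	-0.94
wimley_white_octanol	hydrophobicity	0.50	-0.02	3.64	3.63	-1.71	1.15	2.33	-1.12	2.80	-1.25	-0.67	0.85	0.14	0.77	1.81	0.46	0.25	-0.46	-2.09	-0.71
rose_buried_fraction	hydrophobicity	0.74	0.91	0.62	0.62	0.88	0.72	0.78	0.88	0.52	0.85	0.85	0.63	0.64	0.62	0.64	0.66	0.70	0.86	0.85	0.76
chothia_buried	hydrophobicity	0.38	0.45	0.15	0.18	0.50	0.36	0.17	0.60	0.03	0.45	0.40	0.12	0.18	0.07	0.01	0.22	0.23	0.54	0.27	0.15
bull_breese	hydrophobicity	0.61	0.36	0.61	0.51	-1.52	0.81	0.69	-1.45	0.46	-1.65	-0.66	0.89	-0.17	0.97	0.69	0.42	0.29	-0.75	-1.20	-1.43
guy	hydrophobicity	0.10	-1.42	0.78	0.83	-2.12	0.33	-0.50	-1.13	1.40	-1.18	-1.59	0.48	0.73	0.95	1.91	0.52	0.07	-1.27	-0.51	-0.21
miyazawa_jernigan	hydrophobicity	5.33	7.93	3.59	3.65	9.03	4.48	5.10	8.83	2.95	8.47	8.95	3.71	3.87	3.87	4.18	4.09	4.49	7.63	7.66	5.89
roseman	hydrophobicity	0.39	0.25	-3.81	-2.91	2.27	0.00	-0.64	1.82	-2.77	1.82	0.96	-1.91	0.99	-1.30	-3.95	-1.24	-1.00	1.30	2.13	1.47
wolfenden_hydration	hydrophobicity	1.94	-1.24	-10.95	-10.20	-0.76	2.39	-10.27	2.15	-9.52	2.28	-1.48	-9.68	0.00	-9.38	-19.92	-5.06	-4.88	1.99	-5.88	-6.11
black_mould	hydrophobicity	0.616	0.680	0.028	0.043	1.000	0.501	0.165	0.943	0.283	0.943	0.738	0.236	0.711	0.251	0.000	0.359	0.450	0.825	0.878	0.880
abraham_leo	hydrophobicity	0.44	0.58	-0.31	-0.34	2.54	0.00	-0.01	2.46	-2.45	2.46	1.10	-1.32	1.29	-0.71	-2.42	-0.84	-0.41	1.73	2.56	1.63
cowan_whittaker	hydrophobicity	0.35	0.76	-2.15	-1.95	1.69	0.00	-0.65	1.83	-1.54	1.80	1.10	-0.44	0.84	-0.93	-1.50	-0.63	-0.27	1.32	1.35	0.39
manavalan_ponnuswamy	hydrophobicity	12.97	14.63	10.85	11.89	14.00	12.43	12.16	15.67	11.36	14.90	14.39	11.42	11.37	11.76	11.72	11.23	11.69	15.71	13.93	13.42
sweet_eisenberg_omh	hydrophobicity	-0.40	0.17	-1.31	-1.22	1.92	-0.67	-0.64	1.25	-0.67	1.22	1.02	-0.92	-0.49	-0.91	-0.59	-0.55	-0.28	0.91	0.50	1.67
nozaki_tanford	hydrophobicity	0.5	0.0	0.0	0.0	2.5	0.0	0.5	1.8	0.0	1.8	1.3	0.0	1.4	0.0	0.0	-0.3	0.4	1.5	3.4	2.3
aboderin_mobility	hydrophobicity	5.1	0.0	0.7	1.8	9.6	4.1	1.6	9.3	1.3	10.0	8.7	0.6	4.9	1.4	2.0	3.1	3.5	8.5	9.2	8.0
zimmerman	hydrophobicity	0.83	1.48	0.64	0.65	2.75	0.10	1.10	3.07	1.60	2.52	1.40	0.09	2.70	0.00	0.83	0.14	0.54	1.79	0.31	2.97
meek_hplc_ph7	hydrophobicity	0.5	-6.8	-8.2	-16.9	13.2	0.0	-3.5	13.9	0.1	8.8	4.8	0.8	6.1	-4.8	0.8	1.2	2.7	2.7	14.9	6.1
rao_argos_membrane	hydrophobicity	1.36	1.27	0.11	0.25	1.57	1.09	0.68	1.44	0.09	1.47	1.42	0.33	0.54	0.33	0.15	0.97	1.08	1.37	1.00	0.83
parker_hplc	hydrophobicity	2.1	1.4	10.0	7.8	-9.2	5.7	2.1	-8.0	5.7	-9.2	-4.2	7.0	2.1	6.0	4.2	6.5	5.2	-3.7	-10.0	-1.9
levitt	hydrophobicity	0.6	1.0	-3.0	-3.0	2.5	0.3	-1.3	1.8	-3.0	1.8	1.3	-2.0	-0.3	-0.2	-3.0	-0.1	-0.2	1.5	3.4	2.3
grantham_polarity	polarity	8.1	5.5	13.0	12.3	5.2	9.0	10.4	5.2	11.3	4.9	5.7	11.6	8.0	10.5	10.5	9.2	8.6	5.9	5.4	6.2
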