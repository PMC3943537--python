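acronym	protein	solvent_percent	space_group	cell_a	cell_b	cell_c	cell_alpha	cell_beta	cell_gamma	d_min_A	n_measurements	dose_rate_min_kGy_s	dose_rate_max_kGy_s	beta_ave_A2_MGy	beta_sd	gamma_ave_MGy	gamma_sd	dhalf_norm_ave_MGy	dhalf_norm_sd	role
LYZM	Lysozyme (monoclinic)	34.0	P21	28	63	60	90	90.2	90	1.9	7	0.4	225	15	0.5	1.0	0.2	0.56	0.07	validation
LYZT	Lysozyme (tetragonal)	41.4	P43212	79	79	38	90	90	90	1.9	8	15	294	19	4	2.0	0.3	0.32	0.03	calibration
INSR	Insulin (rhombohedral)	38.3	H3	83	83	109	90	90	120	2.0	4	10	13	24	3	1.0	0.3	0.47	0.06	calibration
INSC	Insulin (cubic)	67.0	I213	79	79	79	90	90	90	2.0	11	0.4	87	32	3	3.6	0.3	0.18	0.01	validation
BPTTR	Trypsin (trigonal)	36.5	P3121	55.9	55.9	109	90	90	120	2.0	8	8	40	13	1	1.1	0.3	0.58	0.10	calibration
BPTOH	Trypsin (orthorhombic, high density)	45.0	P212121	55	59	68	90	90	90	1.7	3	9.6	44	14	3	1.7	0.2	0.40	0.04	calibration
BPTOL	Trypsin (orthorhombic, low density)	56.9	P212121	63	64	69	90	90	90	2.2	10	11	14.3	20	4	2.8	0.4	0.24	0.03	calibration
bR	Bacteriorhodopsin	51.1	P63	62	62	110	90	90	120	3.0	3	1.1	124	29	6	1.0	0.06	0.42	0.05	validation
TIM	Triosephosphate isomerase	52.1	C2	99	53	61	90	118	90	2.5	1	111		33		1.6		0.3		single
THER	Thermolysin	53.8	P6122	95	95	143	90	90	120	2.8	4	17.4	20.4	28	5	0.9	0.2	0.44	0.02	calibration
THAU	Thaumatin	56.8	P41212	59	59	152	90	90	90	2.5	4	11	16	20	2	1.3	0.2	0.43	0.03	validation
FAE	SeMet feruloyl esterase module	63.3	P212121	66	110	114	90	90	90	2.5	5	54	79	34	5	1.2	0.2	0.36	0.06	calibration
6HLNO	6-hydroxy-L-nicotine oxidase	69.7	P432	167	167	167	90	90	90	3.5	3	26.5	28	215	30	3.2	0.3	0.07	0.01	calibration
LACV	L-protein polymerase N-terminal domain	69.9	P6122	125	125	167	90	90	120	3.9	5	27	113	142	20	5.7	1.0	0.08	0.003	validation
TvNiR	Cytochrome c nitrite reductase	77.7	P213	197	197	197	90	90	90	2.6	3	30		11	1	0.6	0.1	0.91	0.09	validation
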