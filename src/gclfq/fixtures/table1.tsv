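gene_symbol	gene_id	gene_name	log2fc_T1_vs_T0	p_T1_vs_T0	log2fc_T2_vs_T1	p_T2_vs_T1	log2fc_T2_vs_T0	p_T2_vs_T0
F10	2159	coagulation factor X	5.15	0.004	-2.96	0.026	2.19	0.207
LSP1	4046	lymphocyte specific protein	4.25	0.004	-2.34	0.062	1.92	0.284
GLUD2	2747	glutamate dehydrogenase 2	4.24	0.009	-2.18	0.038	2.06	0.175
MECP2	4204	methyl-CpG binding protein 2	3.54	0.011	-0.60	0.426	2.94	0.085
TUBB4B	10383	tubulin beta 4B class IVb	6.08	0.014	-2.35	0.255	3.73	0.076
TMEM40	55287	transmembrane protein 40	2.74	0.027	-1.04	0.541	1.70	0.295
H2AFX	3014	H2A.X variant histone	4.06	0.035	-1.36	0.434	2.71	0.259
ACTR3B	57180	actin related protein 3B	2.39	0.041	-1.10	0.393	1.29	0.167
CFHR2	3080	complement factor H related 2	3.08	0.041	-3.08	0.041	ND	ND
HMGA1	3159	high mobility group AT-hook 1	4.36	0.044	-1.94	0.252	2.42	0.270
APOL1	8542	apolipoprotein L1	2.52	0.044	-0.86	0.326	1.66	0.303
HSPA8	3312	heat shock protein family A (Hsp70) member 8	2.01	0.047	-0.61	0.419	1.41	0.322
HIST1H1B	3009	H1.5 linker histone, cluster member	3.16	0.048	-0.29	0.819	2.87	0.140
MYL9	10398	myosin light chain 9	4.92	0.036	-3.54	0.081	1.38	0.628
CALM2	805	calmodulin 2	-2.94	0.015	1.59	0.160	-1.35	0.392
CALM1	801	calmodulin 1	-2.96	0.015	1.60	0.160	-1.36	0.393
CALM3	808	calmodulin 3	-3.01	0.015	1.63	0.161	-1.38	0.394
CD36	948	CD36 molecule	-2.63	0.040	1.85	0.083	-0.78	0.511
FLNC	2318	filamin C	-2.37	0.041	1.62	0.094	-0.75	0.611
RAB1A	5861	RAB1A, member RAS oncogene family	-2.88	0.044	2.21	0.120	-0.67	0.683
APOH	350	apolipoprotein H	-3.68	0.0496	3.06	0.071	-0.62	0.760
H2AFZ	3015	H2A.Z variant histone 1	4.63	0.098	2.15	0.174	6.77	0.004
H2AFV	94239	H2A.Z variant histone 2	4.72	0.098	2.19	0.173	6.91	0.004
SOD2	6648	superoxide dismutase 2	0.51	0.690	4.17	0.013	4.68	0.010
CP	1356	ceruloplasmin	1.62	0.066	0.22	0.518	1.84	0.042
IGLL5	100423062	immunoglobulin lambda like polypeptide 5	2.25	0.221	0.56	0.649	2.81	0.044
KRT77	374454	keratin 77	ND	ND	1.67	0.045	1.67	0.045
ATP1A3	478	ATPase Na+/K+ transporting subunit alpha 3	0.95	0.093	0.30	0.686	1.25	0.048
PPIF	10105	peptidylprolyl isomerase F	-2.59	0.233	-1.74	0.396	-4.33	0.019
ATP5C1	509	ATP synthase F1 subunit gamma	-0.04	0.982	-2.53	0.095	-2.57	0.029
FLOT2	2319	flotillin 2	-0.85	0.454	-1.16	0.193	-2.01	0.039
ABCB11	8647	ATP binding cassette subfamily B member 11	-1.18	0.312	-0.75	0.168	-1.93	0.047
GNG5	2787	G protein subunit gamma 5	-1.05	0.505	-2.80	0.119	-3.85	0.048
APOB	338	apolipoprotein B	-1.01	0.008	-0.16	0.559	-1.18	0.0004
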