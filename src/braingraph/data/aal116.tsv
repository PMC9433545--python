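index	label	hemisphere	network
1	Precentral_L	L	Somatomotor
2	Precentral_R	R	Somatomotor
3	Frontal_Sup_L	L	FPN
4	Frontal_Sup_R	R	FPN
5	Frontal_Sup_Orb_L	L	FPN
6	Frontal_Sup_Orb_R	R	FPN
7	Frontal_Mid_L	L	FPN
8	Frontal_Mid_R	R	FPN
9	Frontal_Mid_Orb_L	L	FPN
10	Frontal_Mid_Orb_R	R	FPN
11	Frontal_Inf_Oper_L	L	FPN
12	Frontal_Inf_Oper_R	R	FPN
13	Frontal_Inf_Tri_L	L	FPN
14	Frontal_Inf_Tri_R	R	FPN
15	Frontal_Inf_Orb_L	L	FPN
16	Frontal_Inf_Orb_R	R	FPN
17	Rolandic_Oper_L	L	Auditory/cingulo-opercular
18	Rolandic_Oper_R	R	Auditory/cingulo-opercular
19	Supp_Motor_Area_L	L	Ventral attention
20	Supp_Motor_Area_R	R	Ventral attention
21	Olfactory_L	L	subcortical
22	Olfactory_R	R	subcortical
23	Frontal_Sup_Medial_L	L	FPN
24	Frontal_Sup_Medial_R	R	FPN
25	Frontal_Med_Orb_L	L	DMN
26	Frontal_Med_Orb_R	R	DMN
27	Rectus_L	L	FPN
28	Rectus_R	R	FPN
29	Insula_L	L	Salience/cingulo-opercular
30	Insula_R	R	Salience/cingulo-opercular
31	Cingulum_Ant_L	L	Salience/cingulo-opercular
32	Cingulum_Ant_R	R	Salience/cingulo-opercular
33	Cingulum_Mid_L	L	Salience/cingulo-opercular
34	Cingulum_Mid_R	R	Salience/cingulo-opercular
35	Cingulum_Post_L	L	DMN
36	Cingulum_Post_R	R	DMN
37	Hippocampus_L	L	subcortical
38	Hippocampus_R	R	subcortical
39	ParaHippocampal_L	L	subcortical
40	ParaHippocampal_R	R	subcortical
41	Amygdala_L	L	subcortical
42	Amygdala_R	R	subcortical
43	Calcarine_L	L	Visual
44	Calcarine_R	R	Visual
45	Cuneus_L	L	Visual
46	Cuneus_R	R	Visual
47	Lingual_L	L	Visual
48	Lingual_R	R	Visual
49	Occipital_Sup_L	L	Visual
50	Occipital_Sup_R	R	Visual
51	Occipital_Mid_L	L	Visual
52	Occipital_Mid_R	R	Visual
53	Occipital_Inf_L	L	Visual
54	Occipital_Inf_R	R	Visual
55	Fusiform_L	L	Visual
56	Fusiform_R	R	Visual
57	Postcentral_L	L	Somatomotor
58	Postcentral_R	R	Somatomotor
59	Parietal_Sup_L	L	FPN
60	Parietal_Sup_R	R	FPN
61	Parietal_Inf_L	L	FPN
62	Parietal_Inf_R	R	FPN
63	SupraMarginal_L	L	FPN
64	SupraMarginal_R	R	FPN
65	Angular_L	L	DMN
66	Angular_R	R	DMN
67	Precuneus_L	L	DMN
68	Precuneus_R	R	DMN
69	Paracentral_Lobule_L	L	Somatomotor
70	Paracentral_Lobule_R	R	Somatomotor
71	Caudate_L	L	subcortical
72	Caudate_R	R	subcortical
73	Putamen_L	L	subcortical
74	Putamen_R	R	subcortical
75	Pallidum_L	L	subcortical
76	Pallidum_R	R	subcortical
77	Thalamus_L	L	subcortical
78	Thalamus_R	R	subcortical
79	Heschl_L	L	Auditory/cingulo-opercular
80	Heschl_R	R	Auditory/cingulo-opercular
81	Temporal_Sup_L	L	Auditory/cingulo-opercular
82	Temporal_Sup_R	R	Auditory/cingulo-opercular
83	Temporal_Pole_Sup_L	L	FPN
84	Temporal_Pole_Sup_R	R	FPN
85	Temporal_Mid_L	L	DMN
86	Temporal_Mid_R	R	DMN
87	Temporal_Pole_Mid_L	L	DMN
88	Temporal_Pole_Mid_R	R	DMN
89	Temporal_Inf_L	L	FPN
90	Temporal_Inf_R	R	FPN
91	Cerebelum_Crus1_L	L	Cerebellum
92	Cerebelum_Crus1_R	R	Cerebellum
93	Cerebelum_Crus2_L	L	Cerebellum
94	Cerebelum_Crus2_R	R	Cerebellum
95	Cerebelum_3_L	L	Cerebellum
96	Cerebelum_3_R	R	Cerebellum
97	Cerebelum_4_5_L	L	Cerebellum
98	Cerebelum_4_5_R	R	Cerebellum
99	Cerebelum_6_L	L	Cerebellum
100	Cerebelum_6_R	R	Cerebellum
101	Cerebelum_7b_L	L	Cerebellum
102	Cerebelum_7b_R	R	Cerebellum
103	Cerebelum_8_L	L	Cerebellum
104	Cerebelum_8_R	R	Cerebellum
105	Cerebelum_9_L	L	Cerebellum
106	Cerebelum_9_R	R	Cerebellum
107	Cerebelum_10_L	L	Cerebellum
108	Cerebelum_10_R	R	Cerebellum
109	Vermis_1_2	M	Cerebellum
110	Vermis_3	M	Cerebellum
111	Vermis_4_5	M	Cerebellum
112	Vermis_6	M	Cerebellum
113	Vermis_7	M	Cerebellum
114	Vermis_8	M	Cerebellum
115	Vermis_9	M	Cerebellum
116	Vermis_10	M	Cerebellum
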