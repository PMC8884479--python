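node_id	node_name	hemisphere	network
1	Precentral_L	left	SMN
2	Precentral_R	right	SMN
3	Frontal_Sup_L	left	DMN
4	Frontal_Sup_R	right	DMN
5	Frontal_Sup_Orb_L	left	LBN
6	Frontal_Sup_Orb_R	right	LBN
7	Frontal_Mid_L	left	FPN
8	Frontal_Mid_R	right	FPN
9	Frontal_Mid_Orb_L	left	LBN
10	Frontal_Mid_Orb_R	right	LBN
11	Frontal_Inf_Oper_L	left	FPN
12	Frontal_Inf_Oper_R	right	FPN
13	Frontal_Inf_Tri_L	left	FPN
14	Frontal_Inf_Tri_R	right	FPN
15	Frontal_Inf_Orb_L	left	LBN
16	Frontal_Inf_Orb_R	right	LBN
17	Rolandic_Oper_L	left	SMN
18	Rolandic_Oper_R	right	SMN
19	Supp_Motor_Area_L	left	SMN
20	Supp_Motor_Area_R	right	SMN
21	Olfactory_L	left	LBN
22	Olfactory_R	right	LBN
23	Frontal_Sup_Medial_L	left	DMN
24	Frontal_Sup_Medial_R	right	DMN
25	Frontal_Med_Orb_L	left	DMN
26	Frontal_Med_Orb_R	right	DMN
27	Rectus_L	left	LBN
28	Rectus_R	right	LBN
29	Insula_L	left	VAN
30	Insula_R	right	VAN
31	Cingulum_Ant_L	left	DMN
32	Cingulum_Ant_R	right	DMN
33	Cingulum_Mid_L	left	VAN
34	Cingulum_Mid_R	right	VAN
35	Cingulum_Post_L	left	DMN
36	Cingulum_Post_R	right	DMN
37	Hippocampus_L	left	LBN
38	Hippocampus_R	right	LBN
39	ParaHippocampal_L	left	LBN
40	ParaHippocampal_R	right	LBN
41	Amygdala_L	left	LBN
42	Amygdala_R	right	LBN
43	Calcarine_L	left	VSN
44	Calcarine_R	right	VSN
45	Cuneus_L	left	VSN
46	Cuneus_R	right	VSN
47	Lingual_L	left	VSN
48	Lingual_R	right	VSN
49	Occipital_Sup_L	left	VSN
50	Occipital_Sup_R	right	VSN
51	Occipital_Mid_L	left	VSN
52	Occipital_Mid_R	right	VSN
53	Occipital_Inf_L	left	VSN
54	Occipital_Inf_R	right	VSN
55	Fusiform_L	left	VSN
56	Fusiform_R	right	VSN
57	Postcentral_L	left	SMN
58	Postcentral_R	right	SMN
59	Parietal_Sup_L	left	DAN
60	Parietal_Sup_R	right	DAN
61	Parietal_Inf_L	left	DAN
62	Parietal_Inf_R	right	DAN
63	SupraMarginal_L	left	VAN
64	SupraMarginal_R	right	VAN
65	Angular_L	left	DMN
66	Angular_R	right	DMN
67	Precuneus_L	left	DMN
68	Precuneus_R	right	DMN
69	Paracentral_Lobule_L	left	SMN
70	Paracentral_Lobule_R	right	SMN
71	Caudate_L	left	DGN
72	Caudate_R	right	DGN
73	Putamen_L	left	DGN
74	Putamen_R	right	DGN
75	Pallidum_L	left	DGN
76	Pallidum_R	right	DGN
77	Thalamus_L	left	DGN
78	Thalamus_R	right	DGN
79	Heschl_L	left	SMN
80	Heschl_R	right	SMN
81	Temporal_Sup_L	left	SMN
82	Temporal_Sup_R	right	SMN
83	Temporal_Pole_Sup_L	left	LBN
84	Temporal_Pole_Sup_R	right	LBN
85	Temporal_Mid_L	left	DMN
86	Temporal_Mid_R	right	DMN
87	Temporal_Pole_Mid_L	left	LBN
88	Temporal_Pole_Mid_R	right	LBN
89	Temporal_Inf_L	left	LBN
90	Temporal_Inf_R	right	LBN
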