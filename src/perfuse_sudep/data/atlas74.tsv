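id	name	hemisphere	partner_id	class
1	superior_frontal_L	left	2	cortical
2	superior_frontal_R	right	1	cortical
3	middle_frontal_L	left	4	cortical
4	middle_frontal_R	right	3	cortical
5	inferior_frontal_L	left	6	cortical
6	inferior_frontal_R	right	5	cortical
7	precentral_L	left	8	cortical
8	precentral_R	right	7	cortical
9	rectus_L	left	10	cortical
10	rectus_R	right	9	cortical
11	medial_orbitofrontal_L	left	12	cortical
12	medial_orbitofrontal_R	right	11	cortical
13	lateral_orbitofrontal_L	left	14	cortical
14	lateral_orbitofrontal_R	right	13	cortical
15	postcentral_L	left	16	cortical
16	postcentral_R	right	15	cortical
17	superior_parietal_L	left	18	cortical
18	superior_parietal_R	right	17	cortical
19	supramarginal_L	left	20	cortical
20	supramarginal_R	right	19	cortical
21	angular_L	left	22	cortical
22	angular_R	right	21	cortical
23	precuneus_L	left	24	cortical
24	precuneus_R	right	23	cortical
25	superior_temporal_L	left	26	cortical
26	superior_temporal_R	right	25	cortical
27	middle_temporal_L	left	28	cortical
28	middle_temporal_R	right	27	cortical
29	inferior_temporal_L	left	30	cortical
30	inferior_temporal_R	right	29	cortical
31	fusiform_L	left	32	cortical
32	fusiform_R	right	31	cortical
33	parahippocampal_L	left	34	cortical
34	parahippocampal_R	right	33	cortical
35	entorhinal_L	left	36	cortical
36	entorhinal_R	right	35	cortical
37	temporal_pole_L	left	38	cortical
38	temporal_pole_R	right	37	cortical
39	superior_occipital_L	left	40	cortical
40	superior_occipital_R	right	39	cortical
41	middle_occipital_L	left	42	cortical
42	middle_occipital_R	right	41	cortical
43	inferior_occipital_L	left	44	cortical
44	inferior_occipital_R	right	43	cortical
45	cuneus_L	left	46	cortical
46	cuneus_R	right	45	cortical
47	lingual_L	left	48	cortical
48	lingual_R	right	47	cortical
49	cingulate_L	left	50	cortical
50	cingulate_R	right	49	cortical
51	insula_L	left	52	cortical
52	insula_R	right	51	cortical
53	hippocampus_L	left	54	subcortical
54	hippocampus_R	right	53	subcortical
55	amygdala_L	left	56	subcortical
56	amygdala_R	right	55	subcortical
57	caudate_L	left	58	subcortical
58	caudate_R	right	57	subcortical
59	putamen_L	left	60	subcortical
60	putamen_R	right	59	subcortical
61	globus_pallidus_L	left	62	subcortical
62	globus_pallidus_R	right	61	subcortical
63	thalamus_L	left	64	subcortical
64	thalamus_R	right	63	subcortical
65	nucleus_accumbens_L	left	66	subcortical
66	nucleus_accumbens_R	right	65	subcortical
67	red_nucleus_L	left	68	subcortical
68	red_nucleus_R	right	67	subcortical
69	substantia_nigra_L	left	70	subcortical
70	substantia_nigra_R	right	69	subcortical
71	cerebellum_hemisphere_L	left	72	subcortical
72	cerebellum_hemisphere_R	right	71	subcortical
73	medulla	midline	73	subcortical
74	pons	midline	74	subcortical
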