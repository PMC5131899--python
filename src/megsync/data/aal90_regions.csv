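order,name,x_mm,y_mm,z_mm,lobe
0,Frontal Inf Orb L,-37,31,-12,Frontal
1,Frontal Inf Orb R,40,32,-12,Frontal
2,Frontal Inf Oper L,-49,13,19,Frontal
3,Frontal Inf Oper R,49,15,21,Frontal
4,Rectus L,-6,37,-18,Frontal
5,Rectus R,7,36,-18,Frontal
6,Frontal Inf Tri L,-47,30,14,Frontal
7,Frontal Inf Tri R,49,30,30,Frontal
8,Frontal Mid L,-34,33,35,Frontal
9,Frontal Mid R,37,33,34,Frontal
10,Frontal Mid Orb L,-32,50,-10,Frontal
11,Frontal Mid Orb R,32,53,-11,Frontal
12,Frontal Med Orb L,-6,54,-7,Frontal
13,Frontal Med Orb R,7,52,-7,Frontal
14,Frontal Sup Orb L,-18,47,-13,Frontal
15,Frontal Sup Orb R,17,48,12,Frontal
16,Frontal Sup Medial L,-6,49,31,Frontal
17,Frontal Sup Medial R,-8,51,30,Frontal
18,Frontal Sup L,-19,35,42,Frontal
19,Frontal Sup R,20,35,44,Frontal
20,Supp Motor Area L,-6,5,61,Frontal
21,Supp Motor Area R,8,0,62,Frontal
22,Precentral L,-40,-6,51,Frontal
23,Precentral R,40,-8,52,Frontal
24,Rolandic Oper L,-48,-8,14,Frontal
25,Rolandic Oper R,52,-6,15,Frontal
26,Insula L,-36,7,3,Frontal
27,Insula R,38,6,2,Frontal
28,Temporal Pole Mid L,-37,15,-34,Temporal
29,Temporal Pole Mid R,43,15,-12,Temporal
30,Temporal Pole Sup L,-41,15,-34,Temporal
31,Temporal Pole Sup R,47,15,-32,Temporal
32,Temporal Sup L,-54,-21,7,Temporal
33,Temporal Sup R,57,-22,7,Temporal
34,Temporal Mid L,-57,-34,-2,Temporal
35,Temporal Mid R,56,-37,-1,Temporal
36,Temporal Inf L,-51,-28,-23,Temporal
37,Temporal Inf R,53,-31,-22,Temporal
38,Heschl L,-42,-19,10,Temporal
39,Heschl R,46,-17,10,Temporal
40,Olfactory L,-9,15,-12,Limbic
41,Olfactory R,8,16,-11,Limbic
42,Cingulum Ant L,-5,35,14,Limbic
43,Cingulum Ant R,7,37,16,Limbic
44,Cingulum Mid L,-6,-15,42,Limbic
45,Cingulum Mid R,7,-9,40,Limbic
46,Cingulum Post L,-6,-43,25,Limbic
47,Cingulum Post R,6,-42,22,Limbic
48,Hippocampus L,-26,-21,-10,Limbic
49,Hippocampus R,28,-20,-10,Limbic
50,ParaHippocampus L,-22,-16,-21,Limbic
51,ParaHippocampus R,24,-15,-20,Limbic
52,Amygdala L,-24,-1,-17,Limbic
53,Amygdala R,26,1,-18,Limbic
54,Caudate L,-12,11,9,Limbic
55,Caudate R,14,12,9,Limbic
56,Putamen L,-25,4,2,Limbic
57,Putamen R,27,5,2,Limbic
58,Pallidum L,-19,0,0,Limbic
59,Pallidum R,20,0,0,Limbic
60,Thalamus L,-12,-18,8,Limbic
61,Thalamus R,12,-18,8,Limbic
62,Paracentral Lobule L,-9,-25,70,Parietal
63,Paracentral Lobule R,6,-32,68,Parietal
64,Postcentral L,-43,-23,49,Parietal
65,Postcentral R,40,-25,53,Parietal
66,Parietal Sup L,-24,-60,59,Parietal
67,Parietal Sup R,25,-59,62,Parietal
68,Parietal Inf L,-44,-46,47,Parietal
69,Parietal Inf R,45,-46,50,Parietal
70,SupraMarginal L,-57,-34,30,Parietal
71,SupraMarginal R,5,-32,34,Parietal
72,Angular L,-45,-61,36,Parietal
73,Angular R,45,-60,39,Parietal
74,Precuneus L,-8,-56,48,Parietal
75,Precuneus R,9,-56,44,Parietal
76,Cuneus L,-7,-80,27,Occipital
77,Cuneus R,13,79,28,Occipital
78,Lingual L,-16,-68,-5,Occipital
79,Lingual R,15,-67,-4,Occipital
80,Fusiform L,-32,-40,-20,Occipital
81,Fusiform R,33,-39,-20,Occipital
82,Calcarine L,-8,-79,6,Occipital
83,Calcarine R,15,-73,9,Occipital
84,Occipital Sup L,-18,-84,28,Occipital
85,Occipital Sup R,23,-81,31,Occipital
86,Occipital Mid L,-33,-81,16,Occipital
87,Occipital Mid R,36,-80,19,Occipital
88,Occipital Inf L,-37,-78,-8,Occipital
89,Occipital Inf R,37,-82,-8,Occipital
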