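index,name,abbreviation,hemisphere,swallowing_roi
0,Precentral gyrus,PreCG,L,0
1,Precentral gyrus,PreCG,R,1
2,Postcentral gyrus,PosCG,L,1
3,Postcentral gyrus,PosCG,R,0
4,Rolandic operculum,ROL,L,0
5,Rolandic operculum,ROL,R,0
6,"Superior frontal gyrus, dorsolateral",SFGdor,L,1
7,"Superior frontal gyrus, dorsolateral",SFGdor,R,1
8,Middle frontal gyrus,MFG,L,1
9,Middle frontal gyrus,MFG,R,1
10,"Inferior frontal gyrus, opercular part",IFGoper,L,0
11,"Inferior frontal gyrus, opercular part",IFGoper,R,0
12,"Inferior frontal gyrus, triangular part",IFGtri,L,0
13,"Inferior frontal gyrus, triangular part",IFGtri,R,0
14,"Superior frontal gyrus, medial",SFGmed,L,0
15,"Superior frontal gyrus, medial",SFGmed,R,0
16,Supplementary motor area,SMA,L,1
17,Supplementary motor area,SMA,R,1
18,Paracentral lobule,PCL,L,1
19,Paracentral lobule,PCL,R,1
20,"Superior frontal gyrus, orbital part",SFGorb,L,0
21,"Superior frontal gyrus, orbital part",SFGorb,R,0
22,"Superior frontal gyrus, medial orbital",SFGmedorb,L,0
23,"Superior frontal gyrus, medial orbital",SFGmedorb,R,0
24,"Middle frontal gyrus, orbital part",MFGorb,L,0
25,"Middle frontal gyrus, orbital part",MFGorb,R,0
26,"Inferior frontal gyrus, orbital part",IFGorb,L,0
27,"Inferior frontal gyrus, orbital part",IFGorb,R,0
28,Gyrus rectus,GRE,L,0
29,Gyrus rectus,GRE,R,0
30,Olfactory cortex,OLF,L,0
31,Olfactory cortex,OLF,R,0
32,Superior temporal gyrus,STG,L,1
33,Superior temporal gyrus,STG,R,1
34,Heschl gyrus,HES,L,0
35,Heschl gyrus,HES,R,0
36,Middle temporal gyrus,MTG,L,0
37,Middle temporal gyrus,MTG,R,0
38,Inferior temporal gyrus,ITG,L,0
39,Inferior temporal gyrus,ITG,R,0
40,Superior parietal gyrus,SPG,L,1
41,Superior parietal gyrus,SPG,R,1
42,"Inferior parietal, but supramarginal and angular gyri",IPL,L,1
43,"Inferior parietal, but supramarginal and angular gyri",IPL,R,1
44,Angular gyrus,ANG,L,0
45,Angular gyrus,ANG,R,0
46,Supramarginal gyrus,SMG,L,1
47,Supramarginal gyrus,SMG,R,1
48,Precuneus,PCUN,L,1
49,Precuneus,PCUN,R,1
50,Superior occipital gyrus,SOG,L,1
51,Superior occipital gyrus,SOG,R,1
52,Middle occipital gyrus,MOG,L,1
53,Middle occipital gyrus,MOG,R,1
54,Inferior occipital gyrus,IOG,L,0
55,Inferior occipital gyrus,IOG,R,0
56,Cuneus,CUN,L,1
57,Cuneus,CUN,R,1
58,Calcarine fissure and surrounding cortex,CAL,L,0
59,Calcarine fissure and surrounding cortex,CAL,R,0
60,Lingual gyrus,LING,L,1
61,Lingual gyrus,LING,R,1
62,Fusiform gyrus,FFG,L,1
63,Fusiform gyrus,FFG,R,0
64,Temporal pole: superior temporal gyrus,TPOstg,L,0
65,Temporal pole: superior temporal gyrus,TPOstg,R,0
66,Temporal pole: middle temporal gyrus,TPO,L,0
67,Temporal pole: middle temporal gyrus,TPO,R,0
68,Anterior cingulate and paracingulate gyri,ACP,L,1
69,Anterior cingulate and paracingulate gyri,ACP,R,1
70,Median cingulate and paracingulate gyri,MCP,L,1
71,Median cingulate and paracingulate gyri,MCP,R,1
72,Posterior cingulate gyrus,PCG,L,1
73,Posterior cingulate gyrus,PCG,R,1
74,Hippocampus,HIP,L,1
75,Hippocampus,HIP,R,1
76,Parahippocampal gyrus,PHG,L,0
77,Parahippocampal gyrus,PHG,R,0
78,Insula,INS,L,1
79,Insula,INS,R,1
80,Amygdala,AMY,L,0
81,Amygdala,AMY,R,0
82,Caudate nucleus,CAU,L,0
83,Caudate nucleus,CAU,R,0
84,"Lenticular nucleus, putamen",PUT,L,1
85,"Lenticular nucleus, putamen",PUT,R,0
86,"Lenticular nucleus, pallidum",PAL,L,0
87,"Lenticular nucleus, pallidum",PAL,R,0
88,Thalamus,THA,L,1
89,Thalamus,THA,R,1
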