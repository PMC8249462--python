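no,territory,male,female,male_natal,female_natal,fp_printed,first_year,last_year,in_study
1,AG,GW187m,GW016f,unk,N,0,2009,2015,1
2,AH,GW194m,GW239f,AG,unk,0,2013,2014,1
3,AH,GW194m,XII,AG,unk,0,2015,2015,1
4,BA,GW243m,GW195f,unk,AG,0,2013,2015,1
5,BE,GW188m,GW191f,AG,AG,0.25,2013,2015,1
6,BI,GW411m,GW541f,unk,DZ,0,2015,2015,1
7,CLH,GW208m,GW340f,AG,unk,0,2013,2013,1
8,CO,GW599m,GW323f,RT,GKL,0.016,2015,2015,1
9,CUN,VIII,GW178f,unk,DN,0,2015,2015,1
10,CUX,GW339m,GW203f,MU,AG,0.055,2015,2015,1
11,DN,GW038m,GW024f,NO,N,0.094,2008,2011,1
12,DN,VI,GW114f,unk,DN,0,2012,2012,1
13,DN,GW038m,GW114f,NO,DN,0.328,2013,2013,1
14,DN,GW301m,GW114f,unk,DN,0,2014,2014,1
15,DN,VII,GW114f,unk,DN,0,2015,2015,1
16,DZ,GW042m,II,unk,unk,0,2006,2008,1
17,DZ,GW042m,GW023f,unk,unk,0,2009,2010,1
18,DZ,GW105m,GW087f,unk,NO,0,2012,2013,1
19,DZ,GW381m,GW087f,unk,NO,0,2014,2015,1
20,ES,GW218m,GW242f,LE,LE,0.25,2014,2014,1
21,ES,XI,GW242f,unk,LE,0,2015,2015,1
22,FHB,GW128m,GW347f,WE,WE,0.156,2014,2014,1
23,GA,GW215m,GW262f,DN,unk,0,2013,2014,1
24,GKL,GW237m,GW196f,unk,AG,0,2012,2015,1
25,GLH,GW250m,GW342f,SPJ,unk,0,2014,2014,1
26,GLH,GW349m,GW342f,SPJ,unk,0,2015,2015,1
27,GR,GW111m,GW245f,KH,unk,0,2013,2015,1
28,GRH,GW149m,GW306f,SPJ,GR,0.008,2015,2015,1
29,HF,GW233m,GW227f,GKL,AG,0.125,2014,2015,1
30,HO,GW283m,GW277f,SP,SP,0.379,2015,2015,1
31,HW,V,GW085f,unk,SL,0,2012,2013,1
32,JW,IV,GW132f,unk,N,0,2011,2011,1
33,KH,GW104m,GW056f,unk,SL,0,2011,2015,1
34,KHB,GW287m,GW116f,MI,DN,0.086,2015,2015,1
35,KN,GW586m,GW180f,unk,MI,0,2015,2015,1
36,KO,GW097m,GW116f,NO,DN,0.203,2013,2013,1
37,LB,III,GW131f,unk,MH,0,2011,2011,1
38,LB,GW144m,GW098f,unk,SP,0,2013,2013,1
39,LB,GW249m,GW098f,unk,SP,0,2014,2014,1
40,LB,GW249m,GW348f,unk,AG,0,2015,2015,1
41,LE,GW161m,GW185f,unk,AG,0,2011,2013,1
42,LE,GW186m,GW185f,AG,AG,0.25,2014,2015,1
43,LH,GW288m,GW293f,DN,KH,0.027,2014,2014,1
44,LH,GW288m,IX,DN,unk,0,2015,2015,1
45,LUE,GW153m,GW258f,unk,unk,0,2014,2015,1
46,MI,GW025m,GW026f,NO,N,0.094,2008,2010,1
47,MI,GW042m,GW026f,unk,N,0,2011,2011,1
48,MI,GW295m,GW026f,unk,N,0,2012,2012,1
49,MI,GW014m,GW026f,DZ,N,0,2013,2015,1
50,MI2,GW014m,GW050f,DZ,MI,0,2012,2012,1
51,MOE,GW333m,XIII,GKL,unk,0,2015,2015,1
52,MU,GW213m,GW214f,SL,NO,0.094,2012,2013,1
53,MU,GW213m,GW263f,SL,MU,0.297,2014,2015,1
54,N,GW001m,GW006f,unk,MH,0,2005,2008,1
55,NO,GW008m,GW012f,MH,MH,0.125,2005,2011,1
56,NO,GW106m,GW071f,unk,NO,0,2012,2013,1
57,NO,GW038m,GW071f,NO,NO,0.313,2014,2015,1
58,NY,GW096m,GW031f,unk,DZ,0,2011,2015,1
59,RM,GW260m,GW202f,unk,AG,0,2014,2014,1
60,RT,GW294m,GW112f,unk,MI,0,2014,2015,1
61,RU,GW404m,X,KH,unk,0,2014,2014,1
62,RU,GW404m,GW177f,KH,DN,0.027,2015,2015,1
63,SE,GW128m,GW130f,WE,N,0.125,2012,2012,1
64,SF,GW362m,GW351f,unk,SPJ,0,2015,2015,1
65,SL,GW014m,GW006f,DZ,MH,0,2009,2011,1
66,SL,GW068m,GW067f,NO,SL,0.094,2013,2014,1
67,SL,GW566m,GW067f,SP,SL,0.102,2015,2015,1
68,SP,GW037m,GW058f,NO,MI,0.203,2011,2015,1
69,SPJ,GW207m,GW140f,unk,WE,0,2012,2015,1
70,STO,GW589m,GW552f,unk,unk,0,2015,2015,1
71,TL,GW246m,GW169f,unk,SP,0,2013,2013,1
72,UEM,GW223m,GW257f,N,GKL,0.063,2014,2015,1
73,WE,GW123m,GW007f,unk,N,0,2009,2010,1
74,WE,GW070m,GW139f,SL,WE,0.063,2012,2012,1
75,WI,GW367m,GW163f,BE,LE,0.125,2015,2015,1
76,ZIH,GW417m,GW497f,unk,CLH,0,2015,2015,1
,MH,I,GW023f,unk,unk,,2000,2001,0
,MH,GW064m,GW023f,unk,unk,,2002,2004,0
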