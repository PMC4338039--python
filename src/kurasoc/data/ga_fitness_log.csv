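generation,best_fitness,mean_fitness
0,0.2503708805740205,0.02620532271745496
1,0.2289912907826979,0.04842602151440842
2,0.203495780312879,0.06661973528514585
3,0.3552842403380339,0.10887354446651878
4,0.35637900225293895,0.1963706972648796
5,0.3576543499229738,0.22067019021022904
6,0.35078706717441266,0.21533331617948623
7,0.3398547204759143,0.19396669998650115
8,0.37927319215588867,0.19749433401291572
9,0.3109822635961885,0.176341377925543
10,0.5080790817428137,0.20517136397128652
11,0.3961938425349809,0.2300225771692696
12,0.3409084997019379,0.2071234700423304
13,0.38651183006794554,0.1899234220875726
14,0.4148708890313601,0.23967625205271278
15,0.3871883616634207,0.2561485044909876
16,0.4091861932692444,0.20141723543965936
17,0.3731232344282045,0.242173930522063
18,0.36202582245305753,0.19639492954412516
19,0.4656642724858659,0.26772533165911705
20,0.4444975016240778,0.24699693866768344
21,0.4702280328921841,0.22389593221908116
22,0.41188355864656795,0.22948026761905332
23,0.4278420875875169,0.23754789382206107
24,0.4847594993583808,0.2320440306743805
25,0.4607829416342819,0.24115248386904758
26,0.4207991740979347,0.25682583052899466
27,0.3608465293727919,0.21705560339572524
28,0.3793437448183363,0.23046424043459535
29,0.38657434542222574,0.24164945526522677
30,0.4498661415912779,0.2645377493754323
31,0.39430752971077193,0.23513885848287944
32,0.34439173271902285,0.2283629215982909
33,0.4480675223493184,0.25258287461899454
34,0.3910605148934661,0.26556188165976446
35,0.3877078571451095,0.2649194310876263
36,0.4262032871832542,0.27096937720152753
37,0.3831951484257643,0.22046766986645744
38,0.39729160926488705,0.269397665188986
39,0.36573181249912706,0.23890290748975862
40,0.459664697292739,0.26140683778415197
41,0.3781894346209807,0.24575976199114852
42,0.35673216249704925,0.2380130628499899
43,0.43157434661619437,0.2619613729119394
44,0.4063507246573972,0.24215656969888127
45,0.3693884288481426,0.2508682981194455
46,0.48477740960522975,0.27126280994197055
47,0.47690102866949474,0.3051173517272296
48,0.4851900267139204,0.31128507364938857
49,0.4199040863820664,0.2631040963446284
50,0.4538875285637504,0.24709917754895247
51,0.4641178711865996,0.2707918399842913
52,0.4803620477043089,0.2792696531929204
53,0.47388905868636294,0.3128153054752244
54,0.3589567209539606,0.2592423164274422
55,0.4626594891270473,0.29836694536685904
56,0.40952543877373265,0.2336830967272169
57,0.43414950330712926,0.29952300258370074
58,0.45069721047177946,0.28605801362716277
59,0.47041052281725326,0.3033047996440442
60,0.4756426694049855,0.2993971841217127
61,0.4398156729230665,0.3047388621239504
62,0.5038484685574932,0.32567479739375865
63,0.4926765060197129,0.2584708484477508
64,0.4806510200159964,0.2957843993092472
65,0.45847835071259824,0.2858760420263269
66,0.37041538395284995,0.27606010578325757
67,0.4677937855513559,0.27686373810528025
68,0.4357612025841608,0.29101284816991
69,0.4603745670860735,0.2847942904400356
70,0.5201964394643678,0.2658575376277106
71,0.504146603582343,0.2835449438590813
72,0.41453122819151417,0.276579468054614
73,0.44716671975591077,0.29939478593412794
74,0.41107366904870024,0.2898116085882884
75,0.48601875674793127,0.3459679649542901
76,0.44346087403767487,0.313822519096021
77,0.424878715323077,0.31864636157931814
78,0.4659472313312684,0.36219992996567496
79,0.47486937831271986,0.30471153101692183
80,0.42541555762375477,0.324182848233352
81,0.4988718779051782,0.32779359769003047
82,0.43928127124502186,0.3087492594348458
83,0.41042113994588325,0.2821381524370101
84,0.45403859375356936,0.34231330035788354
85,0.4780012474701257,0.36775357144081194
86,0.426002569601667,0.2963980452294
87,0.42013609720929107,0.29954407435308217
88,0.502851086644539,0.32373923799885673
89,0.47799151990950395,0.30023562425954764
90,0.5700715969589333,0.32178038238557055
91,0.519778834827551,0.3364537215428388
92,0.4928665857525938,0.3153004488209961
93,0.43905154075770203,0.3396238256660188
94,0.5577599637106035,0.31739622798846834
95,0.5163031550775794,0.3477664382661486
96,0.44890782658900724,0.3339578504224118
97,0.4920101049812613,0.3033394104368591
98,0.46732792606887835,0.3369882031019606
99,0.42241755105972306,0.30714014274505186
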