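age	qx
0	0.0012082694539397032
1	0.0012093146915697073
2	0.0012104814661225705
3	0.0012117839093590543
4	0.0012132377961758811
5	0.0012148607356466945
6	0.001216672384272588
7	0.0012186946840236912
8	0.0012209521280511781
9	0.0012234720572877889
10	0.001226284991523885
11	0.0012294249989677208
12	0.0012329301087580236
13	0.0012368427714218866
14	0.0012412103728458579
15	0.0012460858079760273
16	0.001251528121184342
17	0.0012576032210427357
18	0.0012643846781423829
19	0.001271954615599813
20	0.0012804047030066101
21	0.0012898372658241009
22	0.0013003665236175355
23	0.001312119972070036
24	0.0013252399254453096
25	0.0013398852380968052
26	0.0013562332257636145
27	0.0013744818097911615
28	0.0013948519100793755
29	0.0014175901155309978
30	0.0014429716640863566
31	0.0014713037681118868
32	0.0015029293250157227
33	0.0015382310575291491
34	0.0015776361331716338
35	0.0016216213180683114
36	0.0016707187265667667
37	0.0017255222350770483
38	0.0017866946363045422
39	0.0018549756186428956
40	0.0019311906650195665
41	0.0020162609760537853
42	0.0021112145340657085
43	0.0022171984374038667
44	0.0023354926488277084
45	0.002467525317419228
46	0.002614889850831803
47	0.002779363933730905
48	0.0029629307091774137
49	0.003167802362573191
50	0.0033964463727406136
51	0.0036516147218599304
52	0.0039363763854129985
53	0.004254153455036991
54	0.0046087612812848455
55	0.005004453059659575
56	0.005445969321807187
57	0.005938592834161427
58	0.0064882094482366925
59	0.007101375489578565
60	0.0077853923152729765
61	0.008548388711732025
62	0.009399411843686312
63	0.01034852749986781
64	0.011406930408095928
65	0.012587065408934284
66	0.013902760278339366
67	0.015369370970171548
68	0.017003940001999895
69	0.018825368623470284
70	0.020854603274607086
71	0.023114836648234216
72	0.025631723399589745
73	0.028433610176952673
74	0.03155177915529839
75	0.035020703611468584
76	0.038878313249521956
77	0.04316626592839212
78	0.04793022111405176
79	0.053220108722140336
80	0.05909038497570984
81	0.0656002644130701
82	0.07281391417715366
83	0.08080059313665167
84	0.08963471417485525
85	0.09939580309667029
86	0.11016832204083993
87	0.12204131908634341
88	0.13510785902833233
89	0.14946418329843647
90	0.1652085400980431
91	0.18243961958785704
92	0.2012545242870618
93	0.2217462028716899
94	0.2440002779212752
95	0.2680912069068335
96	0.2940777333960046
97	0.3219976150898263
98	0.3518616602489193
99	0.3836471677086254
100	1.0
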