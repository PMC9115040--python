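# golden SDCS for drude_fixture_elf.tsv at T = 100 eV
# brute-force dense linear-q trapezoid (60000 pts) of the Drude
# closed form; below-grid q clamped to the optical column,
# above-grid q extrapolated ln-ln from the last two grid columns
E_eV	dSdE_per_eV_nm
1	0.0055417576195495996
2	0.0090833448936070409
3	0.012035738596393961
4	0.014750152470248875
5	0.017435211397615044
6	0.020265696560506381
7	0.023431562567425148
8	0.027198238600270402
9	0.032004697056030491
10	0.03854983715598518
11	0.047947213816975386
12	0.061200372734037257
13	0.076248498364003311
14	0.085974942616444103
15	0.084551132098883569
16	0.082490749052440734
17	0.080263894983225448
18	0.077158223180121874
19	0.079136424185994425
20	0.082955818733231781
21	0.082655402150225404
22	0.081001329973719768
23	0.080404956830432556
24	0.080137401959572904
25	0.077128194571611866
26	0.070733372610549225
27	0.064412676285612799
28	0.059240302700747448
29	0.055264996635369948
30	0.052245342281746383
31	0.048328331231979715
32	0.043345223210544535
33	0.03888381114518135
34	0.03523296640152903
35	0.032523869673218894
36	0.030953987461765236
37	0.030140665867499736
38	0.02839776887648322
39	0.025483749944602938
40	0.022719022619250587
41	0.020551411998093041
42	0.019082520450035258
43	0.018316660155877729
44	0.018150119896721436
45	0.018213859164146175
46	0.017431988240237475
47	0.015549090095819403
48	0.013731992588417377
49	0.012433502445169102
50	0.011656762443707419
51	0.011314345804668511
52	0.011270332510958252
53	0.011373400129390285
54	0.011483062975859357
55	0.011160258738047437
56	0.0099828224254348893
57	0.0087222067536646877
58	0.0078715344492782009
59	0.0074199806585425179
60	0.0072725947037771792
61	0.0073134856894669052
62	0.0074035226370227436
63	0.0074327681910743388
64	0.0074062563204793826
65	0.0073073875179630295
66	0.0067480198674782395
67	0.0058678999304729498
68	0.0052239094455183892
69	0.0048971403413142307
70	0.0048115090077066342
71	0.0048814727423297831
72	0.0050046695742051598
73	0.0050675155837902903
74	0.0050051429180996386
75	0.0048685094464593053
76	0.0047821304728029651
77	0.0046601585501515165
78	0.0041833397077253136
79	0.0036476708487338965
80	0.0033396901295991593
81	0.0032417096046696344
82	0.0032891298510679366
83	0.0034126114367027589
84	0.0035274221179633367
85	0.0035474045880993597
86	0.0034376266408525356
87	0.0032511891678969986
88	0.0031007476169730651
89	0.0030677316873037284
90	0.0029934109567038829
91	0.0026463010454543961
92	0.0023059080929031224
93	0.002132717282653226
94	0.0020820437151339841
95	0.0021106438741932887
96	0.002168242463156644
97	0.0021031262294124078
98	0.0016562103907121946
99	0.0007603339003789709
100	0
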