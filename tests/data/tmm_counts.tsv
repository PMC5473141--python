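66	57	40	29
177	269	255	241
444	573	505	490
83	38	50	43
317	120	215	164
307	387	697	440
70	34	35	43
235	213	159	264
351	465	556	685
97	51	21	54
217	182	165	206
380	516	566	298
36	45	43	23
251	181	245	264
371	711	415	481
39	24	43	17
173	172	132	171
424	835	281	391
31	74	62	39
150	352	145	222
487	168	444	628
45	43	60	71
233	233	156	162
534	552	438	446
27	32	25	70
249	66	111	157
602	373	464	441
38	39	22	62
299	292	294	207
288	208	389	409
67	38	62	57
283	256	163	177
612	626	276	577
37	42	43	35
185	149	195	186
437	478	589	612
36	104	39	31
265	189	179	301
417	272	455	189
56	34	33	34
108	132	101	355
609	401	425	326
56	42	47	36
189	208	309	87
432	361	354	404
41	41	20	52
189	207	213	169
339	605	467	330
14	75	58	55
158	212	215	141
468	496	649	419
41	31	55	71
246	171	91	259
496	637	449	751
55	39	85	53
270	156	157	299
312	826	319	577
36	67	25	90
289	181	199	198
474	696	447	741
34	69	79	53
119	249	249	202
283	696	563	335
88	46	65	35
195	250	237	313
516	448	702	657
55	56	78	55
245	259	279	141
455	648	684	470
60	73	62	28
110	342	247	128
763	713	546	465
40	73	63	67
279	187	177	239
602	724	387	578
41	60	62	66
188	212	143	315
273	435	626	619
58	95	25	40
320	235	365	263
213	564	532	614
71	67	56	38
211	92	158	134
326	434	421	569
47	70	35	41
185	230	222	227
512	402	237	560
23	49	88	68
219	148	142	113
570	472	473	421
43	46	83	40
188	149	127	239
440	768	424	869
42	28	78	94
251	250	217	214
468	231	292	790
51	71	22	53
123	315	319	163
308	412	464	526
33	64	68	49
223	220	139	92
282	333	286	476
43	44	53	78
179	225	155	114
361	455	456	687
53	56	59	63
155	203	130	140
292	357	540	487
48	44	40	41
167	236	124	196
586	576	833	694
24	67	75	53
154	186	102	98
464	477	573	472
84	47	33	60
165	110	206	205
391	324	295	393
58	43	42	49
181	139	167	349
294	530	243	412
39	52	67	41
173	188	278	203
349	358	462	616
47	56	53	19
193	264	151	208
771	373	999	499
55	71	62	31
127	181	140	217
426	559	301	451
44	42	85	40
102	174	245	244
420	608	482	412
85	35	32	59
128	183	239	221
626	581	677	417
74	60	48	68
198	123	157	213
549	402	622	622
65	24	53	78
220	140	198	165
347	743	454	431
44	41	53	86
335	119	137	253
473	525	455	543
76	31	30	46
246	361	268	255
422	501	754	414
48	29	60	67
347	175	173	80
544	588	358	405
57	97	23	42
156	301	115	232
426	205	281	261
49	72	75	27
119	263	201	316
323	360	571	439
74	42	51	36
188	193	180	149
340	394	707	721
27	68	29	45
81	131	168	239
484	453	475	883
21	26	33	31
249	175	122	147
357	239	582	761
48	66	62	60
124	223	156	228
370	355	360	653
54	74	50	56
211	131	257	177
585	555	584	454
58	43	39	33
166	252	269	211
573	420	574	514
46	60	56	35
293	212	247	223
481	475	643	573
88	56	27	31
127	221	379	193
805	425	551	446
25	47	50	68
186	208	213	193
152	486	657	362
42	50	53	75
253	244	279	308
563	420	527	363
62	37	49	22
177	133	161	158
356	745	313	551
50	70	63	32
140	170	205	232
275	713	347	473
78	41	83	40
188	249	210	133
481	390	401	169
27	49	53	75
161	106	332	305
943	376	603	503
25	37	61	47
192	92	196	209
407	381	828	559
119	60	59	92
133	147	238	272
473	562	381	570
34	73	31	28
151	147	189	192
475	360	384	553
102	79	44	50
310	207	133	364
732	517	352	420
29	38	63	35
90	176	206	127
638	417	453	706
63	85	28	51
116	214	150	175
735	356	554	688
42	99	47	97
296	236	177	129
392	269	1009	467
79	101	69	30
146	147	190	148
180	311	553	534
39	22	60	55
155	134	238	275
505	408	540	540
48	61	43	57
173	119	121	90
568	469	699	500
73	44	36	49
94	162	120	70
463	567	372	950
70	45	66	97
176	197	102	138
419	682	616	616
67	76	38	51
164	282	158	113
686	525	486	414
38	36	45	70
201	129	166	222
581	535	607	414
66	49	53	51
257	177	182	389
446	622	516	336
43	52	39	36
274	196	283	200
433	449	627	334
38	31	54	40
220	107	251	264
472	607	391	527
63	46	43	59
232	251	304	139
495	279	492	907
66	55	63	79
220	171	175	206
297	451	316	491
45	64	37	43
261	93	56	121
541	169	337	299
40	38	85	46
183	173	132	145
438	669	365	483
31	49	88	63
112	210	101	183
289	640	279	287
63	36	50	84
173	127	134	164
891	478	344	749
30	49	46	56
174	167	183	104
420	430	502	718
54	65	80	44
138	321	162	258
412	368	812	546
44	38	52	42
184	228	249	130
839	310	566	402
45	42	30	66
244	304	167	294
436	254	575	410
49	40	62	46
267	222	202	126
419	345	520	298
37	51	48	57
203	275	202	149
398	692	466	577
46	43	51	35
138	261	136	136
537	502	492	672
44	53	60	43
181	228	418	170
290	307	656	765
51	78	66	31
214	241	131	126
699	528	348	472
55	66	55	54
181	110	220	147
586	554	334	515
70	28	75	60
153	180	301	173
355	214	440	556
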