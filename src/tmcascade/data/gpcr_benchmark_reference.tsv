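# Reference TMD boundary annotations (UniProt-style, 1-based inclusive) for the
# 25-protein GPCR benchmark bundled with tmcascade.  set=known5: five receptors
# of experimentally known structure; set=gpcr20: twenty receptors annotated by
# similarity/potential.  index=SP rows give the annotated signal peptide.
protein_id	set	index	start	end
P47871	known5	SP	1	25
P47871	known5	1	137	161
P47871	known5	2	174	198
P47871	known5	3	226	249
P47871	known5	4	264	285
P47871	known5	5	304	326
P47871	known5	6	351	369
P47871	known5	7	382	402
P34998	known5	SP	1	23
P34998	known5	1	112	142
P34998	known5	2	179	203
P34998	known5	3	219	247
P34998	known5	4	255	282
P34998	known5	5	299	324
P34998	known5	6	336	360
P34998	known5	7	368	397
P07700	known5	1	39	67
P07700	known5	2	77	103
P07700	known5	3	116	137
P07700	known5	4	156	179
P07700	known5	5	206	231
P07700	known5	6	286	315
P07700	known5	7	321	343
P28222	known5	1	50	75
P28222	known5	2	85	110
P28222	known5	3	124	145
P28222	known5	4	166	187
P28222	known5	5	206	228
P28222	known5	6	316	336
P28222	known5	7	350	371
P41595	known5	1	57	79
P41595	known5	2	91	113
P41595	known5	3	130	151
P41595	known5	4	172	192
P41595	known5	5	217	239
P41595	known5	6	325	345
P41595	known5	7	361	382
P21453	gpcr20	1	47	71
P21453	gpcr20	2	79	107
P21453	gpcr20	3	122	140
P21453	gpcr20	4	160	185
P21453	gpcr20	5	202	222
P21453	gpcr20	6	256	277
P21453	gpcr20	7	294	314
P08172	gpcr20	1	23	45
P08172	gpcr20	2	60	80
P08172	gpcr20	3	98	119
P08172	gpcr20	4	140	162
P08172	gpcr20	5	185	207
P08172	gpcr20	6	389	409
P08172	gpcr20	7	424	443
P08483	gpcr20	1	67	90
P08483	gpcr20	2	104	124
P08483	gpcr20	3	142	163
P08483	gpcr20	4	184	206
P08483	gpcr20	5	229	251
P08483	gpcr20	6	492	512
P08483	gpcr20	7	527	546
P25024	gpcr20	1	40	66
P25024	gpcr20	2	76	96
P25024	gpcr20	3	112	133
P25024	gpcr20	4	155	174
P25024	gpcr20	5	200	220
P25024	gpcr20	6	243	264
P25024	gpcr20	7	286	308
P51681	gpcr20	1	31	58
P51681	gpcr20	2	69	89
P51681	gpcr20	3	103	124
P51681	gpcr20	4	142	166
P51681	gpcr20	5	199	218
P51681	gpcr20	6	236	260
P51681	gpcr20	7	278	301
P35367	gpcr20	1	30	49
P35367	gpcr20	2	64	83
P35367	gpcr20	3	102	123
P35367	gpcr20	4	146	165
P35367	gpcr20	5	190	210
P35367	gpcr20	6	419	438
P35367	gpcr20	7	451	470
P41145	gpcr20	1	59	85
P41145	gpcr20	2	96	117
P41145	gpcr20	3	133	154
P41145	gpcr20	4	174	196
P41145	gpcr20	5	223	247
P41145	gpcr20	6	276	299
P41145	gpcr20	7	312	333
P42866	gpcr20	1	65	94
P42866	gpcr20	2	104	121
P42866	gpcr20	3	144	163
P42866	gpcr20	4	194	209
P42866	gpcr20	5	235	257
P42866	gpcr20	6	281	303
P42866	gpcr20	7	312	328
P32300	gpcr20	1	46	75
P32300	gpcr20	2	85	102
P32300	gpcr20	3	125	144
P32300	gpcr20	4	175	190
P32300	gpcr20	5	216	238
P32300	gpcr20	6	262	284
P32300	gpcr20	7	294	310
P41146	gpcr20	1	51	77
P41146	gpcr20	2	88	109
P41146	gpcr20	3	125	146
P41146	gpcr20	4	166	188
P41146	gpcr20	5	212	236
P41146	gpcr20	6	265	288
P41146	gpcr20	7	301	322
P20789	gpcr20	1	65	87
P20789	gpcr20	2	97	121
P20789	gpcr20	3	144	165
P20789	gpcr20	4	189	210
P20789	gpcr20	5	236	260
P20789	gpcr20	6	309	330
P20789	gpcr20	7	349	372
P25116	gpcr20	SP	1	21
P25116	gpcr20	1	103	128
P25116	gpcr20	2	138	157
P25116	gpcr20	3	177	198
P25116	gpcr20	4	219	239
P25116	gpcr20	5	269	288
P25116	gpcr20	6	312	334
P25116	gpcr20	7	351	374
Q8TCB6	gpcr20	1	28	48
Q8TCB6	gpcr20	2	57	77
Q8TCB6	gpcr20	3	102	122
Q8TCB6	gpcr20	4	142	162
Q8TCB6	gpcr20	5	199	219
Q8TCB6	gpcr20	6	239	259
Q8TCB6	gpcr20	7	275	295
Q99835	gpcr20	SP	1	27
Q99835	gpcr20	1	234	254
Q99835	gpcr20	2	263	283
Q99835	gpcr20	3	315	335
Q99835	gpcr20	4	359	379
Q99835	gpcr20	5	403	423
Q99835	gpcr20	6	452	472
Q99835	gpcr20	7	525	545
Q9UJ42	gpcr20	1	24	44
Q9UJ42	gpcr20	2	59	79
Q9UJ42	gpcr20	3	94	114
Q9UJ42	gpcr20	4	137	157
Q9UJ42	gpcr20	5	178	198
Q9UJ42	gpcr20	6	245	265
Q9UJ42	gpcr20	7	269	289
Q9Y5N1	gpcr20	1	40	60
Q9Y5N1	gpcr20	2	71	91
Q9Y5N1	gpcr20	3	109	129
Q9Y5N1	gpcr20	4	157	177
Q9Y5N1	gpcr20	5	197	217
Q9Y5N1	gpcr20	6	360	380
Q9Y5N1	gpcr20	7	396	416
Q9H3N8	gpcr20	1	20	40
Q9H3N8	gpcr20	2	53	73
Q9H3N8	gpcr20	3	88	108
Q9H3N8	gpcr20	4	132	152
Q9H3N8	gpcr20	5	173	193
Q9H3N8	gpcr20	6	305	325
Q9H3N8	gpcr20	7	342	362
Q8NFJ5	gpcr20	1	34	54
Q8NFJ5	gpcr20	2	69	89
Q8NFJ5	gpcr20	3	98	118
Q8NFJ5	gpcr20	4	130	150
Q8NFJ5	gpcr20	5	177	197
Q8NFJ5	gpcr20	6	213	233
Q8NFJ5	gpcr20	7	248	268
Q9GZP7	gpcr20	1	57	77
Q9GZP7	gpcr20	2	85	105
Q9GZP7	gpcr20	3	133	153
Q9GZP7	gpcr20	4	170	190
Q9GZP7	gpcr20	5	227	247
Q9GZP7	gpcr20	6	275	295
Q9GZP7	gpcr20	7	304	324
P35414	gpcr20	1	27	51
P35414	gpcr20	2	67	91
P35414	gpcr20	3	101	125
P35414	gpcr20	4	145	166
P35414	gpcr20	5	201	221
P35414	gpcr20	6	245	271
P35414	gpcr20	7	285	308
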