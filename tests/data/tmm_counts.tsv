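	A	B	C	D
G000	87	272	80	3144
G001	18	47	25	595
G002	133	442	196	5332
G003	153	452	182	6778
G004	8	22	5	206
G005	11	31	11	8
G006	61	197	62	59
G007	32	95	37	36
G008	49	150	61	47
G009	22	67	12	20
G010	168	448	173	162
G011	136	444	146	132
G012	50	170	55	60
G013	188	603	224	216
G014	95	273	99	96
G015	19	62	30	19
G016	90	255	92	94
G017	16	53	11	22
G018	161	491	158	139
G019	40	163	52	60
G020	48	116	50	39
G021	27	70	16	19
G022	226	709	254	248
G023	56	164	56	43
G024	27	116	41	34
G025	37	109	36	32
G026	116	284	93	110
G027	91	250	81	88
G028	93	273	125	81
G029	96	291	87	81
G030	707	2181	733	718
G031	33	86	37	33
G032	23	97	36	20
G033	22	62	21	20
G034	133	367	120	102
G035	205	628	242	235
G036	47	140	52	42
G037	12	70	28	20
G038	20	55	18	20
G039	121	372	116	110
G040	125	370	177	138
G041	105	319	115	110
G042	32	83	35	14
G043	73	200	60	73
G044	67	172	62	72
G045	75	197	67	78
G046	166	472	172	155
G047	86	210	64	73
G048	119	370	163	118
G049	67	194	58	60
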