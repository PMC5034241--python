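pdb_id	g_prime	g_mean	n_residues	human
1M0D	-2.0	-1.65	129	0
2J6G	-1.79	-2.08	260	0
2XDP	-1.75	-2.23	123	1
2Z0W	-1.67	-1.79	72	1
1I1D	-1.42	-1.26	156	0
2P1J	-1.34	-1.42	164	0
1LGP	-1.32	-1.28	113	1
1NPB	-1.3	-1.08	140	0
1LOM	-1.22	-1.45	101	0
2BZY	-1.19	-1.43	62	1
1KLL	-1.16	-0.78	125	0
1HW7	-1.13	-1.44	229	0
1BYL	-1.06	-1.12	122	0
1MI7	-1.05	-0.97	103	0
1BUO	-1.03	-0.99	121	1
1O4W	-0.95	-1.34	123	0
1MU4	-0.94	-1.09	86	0
1W5F	-0.92	-0.48	315	0
1FRO	-0.88	-1.08	176	1
2VAJ	-0.88	-0.52	93	1
1HT9	-0.82	-0.87	76	0
3FSV	-0.79	-0.38	119	0
1ZK9	-0.78	-0.69	110	0
3LOW	-0.73	-0.63	100	1
1T92	-0.66	-0.61	108	0
2ES0	-0.65	-0.54	131	1
2RCZ	-0.53	-0.55	79	1
1KAE	-0.51	-0.46	427	0
1NIR	-0.51	-0.5	538	0
1PUC	-0.49	-0.47	101	0
1HUL	-0.49	-0.66	108	1
1I4M	-0.48	-0.41	108	1
2NU5	-0.43	-0.63	123	0
3LYQ	-0.42	-0.74	184	0
2GUD	-0.41	-0.63	122	0
1R7H	-0.39	-0.57	74	0
1ZXK	-0.38	-0.14	96	0
1K51	-0.35	-0.47	72	0
2A62	-0.35	-0.13	319	0
1N9J	-0.35	-0.32	98	1
1K4Z	-0.33	-0.42	157	0
1TIJ	-0.33	-0.22	114	1
1ZVN	-0.32	-0.13	99	0
2A4E	-0.28	-0.25	208	0
1DXX	-0.27	-0.17	238	1
1K04	-0.27	-0.63	142	1
3FJ5	-0.2	-0.23	58	0
1CTS	-0.17	-0.5	437	0
1FOL	-0.17	-0.35	416	0
2BI4	-0.15	-0.02	382	0
2ONT	-0.15	-0.09	73	1
2CI8	-0.14	-0.61	106	1
1DWW	-0.12	-0.29	420	0
1QQ2	-0.12	-0.4	173	0
1XMM	-0.1	-0.32	288	1
1Q8M	-0.09	0.31	121	1
1GT1	-0.08	-0.1	158	0
1NNQ	-0.07	0.26	170	0
3D94	-0.07	-0.04	289	1
2IV0	-0.04	-0.04	412	0
2W1T	-0.04	-0.07	175	0
1L5X	-0.03	-0.04	270	0
2E6U	-0.03	-0.02	142	0
2O7M	-0.03	-0.04	153	0
4AEO	-0.03	0.0	353	0
3PSN	-0.02	-0.03	183	0
1HE7	-0.02	-0.06	114	1
1U4N	-0.01	0.3	308	0
1UKM	-0.01	-0.01	131	0
1YGT	-0.01	-0.12	104	0
1XUZ	0.0	0.04	348	0
2PA7	0.0	-0.04	135	0
1VJ5	0.0	0.0	547	1
2JFL	0.0	0.0	286	1
1BJ3	0.02	0.0	129	0
2QYP	0.02	0.0	78	1
1X2W	0.03	0.01	129	0
1QB3	0.05	0.0	113	0
1AOJ	0.09	0.29	60	0
1S8O	0.1	0.23	545	1
1CDC	0.13	0.23	96	0
1WY9	0.16	-0.03	111	0
3NG2	0.17	0.25	66	0
2HZL	0.19	0.59	338	0
2FPN	0.2	2.72	198	0
2CN4	0.26	0.6	173	0
2SPC	0.29	0.6	107	0
1R5C	0.31	0.5	124	0
2CO3	0.34	0.53	142	0
2OQR	0.34	0.3	227	0
1H8X	0.35	0.44	125	1
3HXS	0.36	-0.14	120	0
1GP9	0.41	0.54	170	1
2FQM	0.49	0.49	65	0
2DSC	0.49	0.51	195	1
1SK4	0.56	0.77	162	1
2DI3	0.62	0.49	231	0
2NZ7	0.63	0.55	93	1
2HN1	0.66	1.0	246	0
1OSY	0.71	1.0	114	0
2A9U	0.76	0.86	133	1
1A2W	0.78	0.83	124	0
1QX7	0.81	1.08	136	0
1QX5	0.83	1.09	145	0
1MV8	0.86	1.0	436	0
1QWI	0.93	1.12	140	0
1WKQ	1.13	1.06	158	0
1E7L	1.26	1.37	166	0
3DIE	1.5	1.41	106	0
1ILK	1.68	1.63	151	1
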