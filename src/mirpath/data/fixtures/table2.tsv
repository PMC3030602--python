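mirna_id	timepoint	direction	fold_induction	source_table
mmu-miR-712*	ST	up	5.24	table2
mmu-miR-122	ST	up	5.08	table2
mmu-miR-181d	ST	up	2.51	table2
mmu-miR-106a	ST	up	2.28	table2
mmu-miR-223	ST	up	1.99	table2
mmu-miR-146b	ST	up	1.91	table2
mmu-miR-181b	ST	up	1.91	table2
mmu-miR-689	ST	up	1.90	table2
mmu-miR-20b	ST	up	1.88	table2
mmu-miR-451	ST	up	1.60	table2
mmu-miR-100	ST	up	1.52	table2
mmu-miR-187	ST	down	0.66	table2
mmu-miR-497	ST	down	0.49	table2
mmu-miR-690	ST	down	0.49	table2
mmu-miR-1	ST	down	0.46	table2
mmu-miR-483	ST	down	0.39	table2
mmu-miR-574-5p	ST	down	0.37	table2
mmu-miR-203	ST	down	0.35	table2
mmu-miR-672	ST	down	0.35	table2
mmu-miR-805	ST	down	0.28	table2
mmu-miR-155	IT	up	4.48	table2
mmu-miR-467b*	IT	up	2.97	table2
mmu-miR-467a*	IT	up	2.79	table2
mmu-miR-466g	IT	up	2.64	table2
mmu-miR-466f-3p	IT	up	2.23	table2
mmu-miR-455	IT	up	2.03	table2
mmu-miR-150	IT	up	1.80	table2
mmu-miR-423-5p	IT	up	1.69	table2
mmu-miR-146b	IT	up	1.55	table2
mmu-miR-375	IT	up	1.52	table2
mmu-miR-322	IT	down	0.66	table2
mmu-miR-429	IT	down	0.66	table2
mmu-miR-199a-3p	IT	down	0.63	table2
mmu-miR-152	IT	down	0.63	table2
mmu-miR-29c	IT	down	0.62	table2
mmu-miR-218	IT	down	0.62	table2
mmu-miR-200a	IT	down	0.59	table2
mmu-miR-10a	IT	down	0.59	table2
mmu-miR-10b	IT	down	0.53	table2
mmu-miR-29b	IT	down	0.52	table2
mmu-miR-101a	IT	down	0.36	table2
mmu-miR-223	IT	down	0.32	table2
mmu-miR-19b	IT	down	0.31	table2
mmu-miR-690	IT	down	0.24	table2
mmu-miR-450a-5p	IT	down	0.19	table2
mmu-miR-126-5p	IT	down	0.14	table2
mmu-miR-705	LT	up	119.30	table2
mmu-miR-188-5p	LT	up	117.39	table2
mmu-miR-483	LT	up	115.80	table2
mmu-miR-669c	LT	up	115.25	table2
mmu-miR-568	LT	up	96.03	table2
mmu-miR-467b*	LT	up	48.35	table2
mmu-miR-691	LT	up	42.50	table2
mmu-miR-671-5p	LT	up	39.54	table2
mmu-miR-467a*	LT	up	39.02	table2
mmu-miR-485*	LT	up	33.41	table2
mmu-miR-744	LT	up	29.56	table2
mmu-miR-466f-3p	LT	up	22.69	table2
mmu-miR-685	LT	up	19.58	table2
mmu-miR-709	LT	up	18.98	table2
mmu-miR-467e*	LT	up	18.51	table2
mmu-miR-466c-5p	LT	up	17.07	table2
mmu-miR-466g	LT	up	16.19	table2
mmu-miR-574-3p	LT	up	15.99	table2
mmu-miR-574-5p	LT	up	13.18	table2
mmu-miR-667	LT	up	13.13	table2
mmu-miR-713	LT	up	11.83	table2
mmu-let-7d*	LT	up	11.72	table2
mmu-miR-762	LT	up	11.22	table2
mmu-miR-466d-3p	LT	up	9.95	table2
mmu-miR-466b-3-3p	LT	up	9.89	table2
mmu-miR-466f-5p	LT	up	9.50	table2
mmu-miR-297a*	LT	up	9.21	table2
mmu-miR-468	LT	up	8.99	table2
mmu-miR-466a-3p	LT	up	8.48	table2
mmu-miR-197	LT	up	8.06	table2
mmu-miR-455	LT	up	7.51	table2
mmu-miR-877*	LT	up	6.41	table2
mmu-miR-297a	LT	up	6.38	table2
mmu-miR-15a*	LT	up	6.14	table2
mmu-miR-207	LT	up	6.03	table2
mmu-miR-346	LT	up	5.84	table2
mmu-miR-466h	LT	up	5.54	table2
mmu-miR-206	LT	up	5.48	table2
mmu-miR-328	LT	up	5.38	table2
mmu-miR-672	LT	up	5.30	table2
mmu-miR-214	LT	up	5.29	table2
mmu-miR-320	LT	up	4.52	table2
mmu-miR-34c*	LT	up	4.26	table2
mmu-miR-423-5p	LT	up	4.04	table2
mmu-miR-674	LT	up	3.84	table2
mmu-miR-151-3p	LT	up	3.18	table2
mmu-miR-143	LT	up	2.86	table2
mmu-miR-146b	LT	up	2.69	table2
mmu-miR-720	LT	up	2.69	table2
mmu-miR-146a	LT	up	2.09	table2
mmu-miR-99b	LT	up	2.03	table2
mmu-miR-125b-5p	LT	up	1.88	table2
mmu-miR-145	LT	up	1.75	table2
mmu-miR-30d	LT	up	1.64	table2
mmu-miR-191	LT	up	1.59	table2
mmu-miR-200b	LT	down	0.61	table2
mmu-miR-92a	LT	down	0.60	table2
mmu-miR-30c	LT	down	0.59	table2
mmu-miR-27a	LT	down	0.53	table2
mmu-let-7e	LT	down	0.50	table2
mmu-miR-21	LT	down	0.47	table2
mmu-miR-25	LT	down	0.46	table2
mmu-miR-30b	LT	down	0.44	table2
mmu-miR-23b	LT	down	0.41	table2
mmu-miR-23a	LT	down	0.38	table2
mmu-miR-26b	LT	down	0.31	table2
mmu-miR-98	LT	down	0.20	table2
mmu-miR-15a	LT	down	0.19	table2
mmu-miR-29c	LT	down	0.11	table2
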