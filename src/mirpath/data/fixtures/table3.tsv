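mirna_id	fi_st	fi_it	fi_lt	source_table
mmu-miR-690	0.49	0.24		table3
mmu-miR-223	1.99	0.32		table3
mmu-miR-672	0.35		5.31	table3
mmu-miR-574-5p	0.37		13.18	table3
mmu-miR-483	0.39		116.16	table3
mmu-miR-29c		0.62	0.11	table3
mmu-miR-423-5p		1.69	4.03	table3
mmu-miR-455		2.03	7.52	table3
mmu-miR-466f-3p		2.23	22.63	table3
mmu-miR-466g		2.64	16.22	table3
mmu-miR-467a*		2.79	39.12	table3
mmu-miR-467b*		2.97	48.50	table3
mmu-miR-146b	1.91	1.55	2.69	table3
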