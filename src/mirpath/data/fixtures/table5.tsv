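timepoint	mirna_id	mirna_fi	gene_id	gene_fi	process	prediction_p	source_table
ST	mmu-miR-146b	1.91	ALS2CL	0.59	GTPase activator activity	0.0035	table5
ST	mmu-miR-146b	1.91	AP4S1	0.57	Vesicle mediated transport	0.0028	table5
ST	mmu-miR-146b	1.91	APLP2	0.48	ECM organization	0.0097	table5
ST	mmu-miR-146b	1.91	CARD10	0.55	Apoptosis/NF-kB activation	0.0003	table5
ST	mmu-miR-146b	1.91	CFLAR	0.66	Apoptosis/NF-kB activation	0.0371	table5
ST	mmu-miR-146b	1.91	CLEC4D	0.39	Immune response	0.0016	table5
ST	mmu-miR-146b	1.91	GPR116	0.57	Cell signalling	0.0038	table5
ST	mmu-miR-146b	1.91	KLF13	0.66	Transcription regulation	0.0436	table5
ST	mmu-miR-146b	1.91	NCOA4	0.64	Nuclear receptor activator	0.0191	table5
ST	mmu-miR-146b	1.91	NUMB	0.62	Cell signalling	0.0089	table5
ST	mmu-miR-146b	1.91	RASIP1	0.66	Angiogenesis	0.0000	table5
ST	mmu-miR-146b	1.91	SCUBE2	0.52	Inflammation	0.0002	table5
ST	mmu-miR-146b	1.91	TCFCP2L1	0.57	Transcription regulation	0.0391	table5
ST	mmu-miR-146b	1.91	TNFSF9	0.59	Immune response	0.0021	table5
ST	mmu-miR-146b	1.91	UBR1	0.66	Protein metabolism	0.0001	table5
ST	mmu-miR-146b	1.91	UTRN	0.64	Cell signalling	0.0095	table5
ST	mmu-miR-146b	1.91	ZFP451	0.57	Transcription regulation	0.0003	table5
IT	mmu-miR-146b	1.56	BAIAP2L1	0.66	Cell signalling	0.0004	table5
IT	mmu-miR-146b	1.56	FOXP4	0.52	Transcription regulation	0.0134	table5
IT	mmu-miR-146b	1.56	HIST2H3C2	0.52	Nucleosome assembly	0.0371	table5
IT	mmu-miR-146b	1.56	PKP2	0.62	Cell interaction	0.0010	table5
IT	mmu-miR-146b	1.56	ZNHIT1	0.64	Unknown	0.0084	table5
LT	mmu-miR-146b	2.69	BTF3	0.64	Transcription regulation	0.0367	table5
LT	mmu-miR-146b	2.69	CDCA3	0.44	Cell cycle	0.0300	table5
LT	mmu-miR-146b	2.69	DTYMK	0.62	Nucleotide biosynthesis	0.0052	table5
LT	mmu-miR-146b	2.69	HMGCS1	0.66	Lipidic metabolism	0.0069	table5
LT	mmu-miR-146b	2.69	HORMAD1	0.47	Cell cycle	0.0046	table5
LT	mmu-miR-146b	2.69	KIF22	0.29	Microtubules	0.0036	table5
LT	mmu-miR-146b	2.69	MGEA6	0.55	Unknown	0.0230	table5
LT	mmu-miR-146b	2.69	RPS9	0.62	Protein metabolism	0.0001	table5
LT	mmu-miR-146b	2.69	UBE2D2	0.62	Protein metabolism	0.0418	table5
LT	mmu-miR-146b	2.69	WDR12	0.59	Cell signalling	0.0261	table5
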