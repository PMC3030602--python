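mirna_id	gene_id	timepoint	mirna_fi	gene_fi	prediction_p	process	source_table
mmu-miR-223	ARID4B	ST	1.99	0.64	0.0009	Transcription regulation	table4
mmu-miR-223	ARID4B	IT	0.32	19.70	0.0009	Transcription regulation	table4
mmu-miR-223	CFLAR	ST	1.99	0.66	0.0068	Apoptosis	table4
mmu-miR-223	CFLAR	IT	0.32	4.44	0.0068	Apoptosis	table4
mmu-miR-223	IL6	ST	1.99	0.47	0.0110	Inflammation	table4
mmu-miR-223	IL6	IT	0.32	2.00	0.0110	Inflammation	table4
mmu-miR-223	LPIN2	ST	1.99	0.57	0.0050	Transcription regulation	table4
mmu-miR-223	LPIN2	IT	0.32	2.14	0.0050	Transcription regulation	table4
mmu-miR-690	2010001M09RIK	ST	0.49	6.06	0.0283	Apoptosis	table4
mmu-miR-690	2010001M09RIK	IT	0.24	2.00	0.0283	Apoptosis	table4
mmu-miR-690	CDCA8	ST	0.49	3.03	0.0472	Cell cycle	table4
mmu-miR-690	CDCA8	IT	0.24	1.87	0.0472	Cell cycle	table4
mmu-miR-690	CTSE	ST	0.49	1.57	0.0092	Immune response	table4
mmu-miR-690	CTSE	IT	0.24	2.73	0.0092	Immune response	table4
mmu-miR-690	FST	ST	0.49	1.87	0.0008	Cell differentiation	table4
mmu-miR-690	FST	IT	0.24	2.64	0.0008	Cell differentiation	table4
mmu-miR-29c	COL6A2	IT	0.62	1.80	0.0000	Extracellular matrix	table4
mmu-miR-29c	COL6A2	LT	0.11	1.87	0.0000	Extracellular matrix	table4
mmu-miR-29c	CTSK	IT	0.62	1.87	0.0007	Protein metabolism	table4
mmu-miR-29c	CTSK	LT	0.11	1.80	0.0007	Protein metabolism	table4
mmu-miR-29c	METRNL	IT	0.62	2.30	0.0041	Cell differentiation	table4
mmu-miR-29c	METRNL	LT	0.11	1.62	0.0041	Cell differentiation	table4
mmu-miR-483	GMNN	ST	0.39	1.62	0.0455	Transcription regulation	table4
mmu-miR-483	GMNN	LT	116.16	0.55	0.0455	Transcription regulation	table4
mmu-miR-483	MKI67	ST	0.39	2.64	0.00147	Cell division	table4
mmu-miR-483	MKI67	LT	116.16	0.45	0.00147	Cell division	table4
mmu-miR-483	NOLA2	ST	0.39	1.74	0.0300	Ribosome biogenesis	table4
mmu-miR-483	NOLA2	LT	116.16	0.55	0.0300	Ribosome biogenesis	table4
mmu-miR-483	UBE2C	ST	0.39	2.46	0.0012	Protein metabolism	table4
mmu-miR-483	UBE2C	LT	116.16	0.39	0.0012	Protein metabolism	table4
mmu-miR-574-5p	CCNB1	ST	0.37	4.76	0.0339	Cell cycle	table4
mmu-miR-574-5p	CCNB1	LT	13.18	0.10	0.0339	Cell cycle	table4
mmu-miR-574-5p	CDCA8	ST	0.37	3.03	0.0006	Cell cycle	table4
mmu-miR-574-5p	CDCA8	LT	13.18	0.35	0.0006	Cell cycle	table4
mmu-miR-574-5p	DERA	ST	0.37	1.57	0.0058	Nucleotide synthesis	table4
mmu-miR-574-5p	DERA	LT	13.18	0.66	0.0058	Nucleotide synthesis	table4
mmu-miR-574-5p	NUSAP1	ST	0.37	2.00	0.0477	Cell cycle	table4
mmu-miR-574-5p	NUSAP1	LT	13.18	0.28	0.0477	Cell cycle	table4
mmu-miR-672	CD3G	ST	0.35	1.74	0.0054	Immune response	table4
mmu-miR-672	CD3G	LT	5.31	0.32	0.0054	Immune response	table4
mmu-miR-672	PHB2	ST	0.35	1.68	0.0042	Transcription regulation	table4
mmu-miR-672	PHB2	LT	5.31	0.66	0.0042	Transcription regulation	table4
mmu-miR-672	PPP1R14B	ST	0.35	1.74	0.0069	Cell signalling	table4
mmu-miR-672	PPP1R14B	LT	5.31	0.62	0.0069	Cell signalling	table4
mmu-miR-672	TOP2A	ST	0.35	2.46	0.0037	Transcription regulation	table4
mmu-miR-672	TOP2A	LT	5.31	0.29	0.0037	Transcription regulation	table4
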