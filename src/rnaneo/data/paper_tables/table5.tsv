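neoantigen_id	hla_allele	allele_frequency	amino_acid_change	gene_symbol	peptide_position	mut_mhc_ic50	priority_score	augmented_peptide	synthesis_failed	cross_ref
H1	DRB1_1501	0.667	E/K	DEPDC1	10	180.15	39	SFKSTECLLLSLLHRKKNKEESDSTERLQIS	False
H2	HLA-DPA10202-DPB10202	0.646	L/P	PSPH	14	51.57	32	GFGGNVIRQQVKDNAKWYITDFVELLGEPEE	False
H3	DRB1_1501	0.833333	I/M	ZNF587B	10	159.69	13	HQRFGRPRWVDHKDRKEFKTSLGNMVKSCLF	False
H4	HLA-B15:27	0.181818	G/E	WDR7	7	991.1	9	LLCSGPSENGQTWTGEDFVSSDKVIIWTENG	False
H5	HLA-B15:27	0.0512821	K/E	SYNC	5	1471.4	3	ERQRQLRNGVQLQQQENKEMEQLRLSLAEEL	False
H6	DRB1_1501	0.0327869	Q/R	TGIF2	14	63.76	2	RDWLYLHRYNAYPSEREKLSLSGQTNLSVLQ	False
H7	HLA-A02:07	0.0363636	N/D	UCHL3	7	1599.2	2	MEGQRWLPLEADPEVTNQFLKQLGLHPNWQF	False
H8	HLA-B15:27	0.0350877	A/P	IGSF3	3	1248	2	FQRLSPVLYRLTVLQPSPQDTGNYSCHVEEW	False
H9	HLA-DQA10303-DQB10602	0.15	R/W	PCNT	5	1291.82	1	HLQGVQDGDLEADTEWAARVLGLETEHKVQL	False
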