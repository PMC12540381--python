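neoantigen_id	hla_allele	allele_frequency	amino_acid_change	gene_symbol	peptide_position	mut_mhc_ic50	priority_score	augmented_peptide	synthesis_failed	cross_ref
LC1	H-2-Db	1	S/L	Smtn	9	129.6	100	VEAPVSSEPLPHPLEAPSPEPPMSPVP	False
LC2	H-2-Kb	0.996	P/S	Eya3	1	16.6	100	AHILSVPVSETTYSGQTQYQTLQQSQP	False
LC3	H-2-Db	1	T/M	Emc1	9	121.4	100	LARDEFNLQKMMVMVTASGKLFGIESS	True	LR3
LC4	H-2-Kb	1	D/G	Leprot	7	280.2	99	VSAFGLPVVLARVGVIKWGACGLVLAG	False
LC5	H-2-Db	1	P/S	Zmym1	2	116.1	99	ACSSSYNSAVMESSSVNVSMVHSSSKE	True
LC6	H-2-IAb	1	T/A	C77080	14	73.3	89	VLAAPAVAPGQVSAIDTSPASPSMPQT	False
LC7	H-2-IAb	1	T/A	Ewsr1	2	79.2	89	QAYSQPVQGYGTGAYDSTTATVTTTQA	False
LC8	H-2-IAb	1	Y/S	Arid1a	6	84.2	88	QRTLLDPGRFTKVSSPAHTEEEEEEHL	False
LC9	H-2-IAb	1	N/S	Gale	1	24.5	70	IQLLEIMRAHGVKSLVFSSSATVYGNP	True
LC10	H-2-IAb	0.723	E/K	Tpd52	3	406.5	64	KVGGAKPAGGDFGKVLNSTANATSTMT	False
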