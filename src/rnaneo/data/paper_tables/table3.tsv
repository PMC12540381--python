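neoantigen_id	hla_allele	allele_frequency	amino_acid_change	gene_symbol	peptide_position	mut_mhc_ic50	priority_score	augmented_peptide	synthesis_failed	cross_ref
LR1	H-2-Kb	0.996	V/A	Ndufs6	2	15.6	36	AALTFRRLLTLPRAARGFGVQVSPSGE	False
LR2	H-2-Kb	0.725	P/S	Plekho1	2	121.4	19	SLSRPWEKPDKGASYTPQALKKFPSTE	False
LR3	H-2-Kb	1	T/M	Emc1	2	471.3	17	LARDEFNLQKMMVMVTASGKLFGIESS	True	LC3
LR4	H-2-Kb	0.552	G/V	Tmem101	1	52.6	17	ALQLAISTYTAYIVGYVHYGDWLKVRM	False
LR5	H-2-Kb	0.711	E/K	Asap1	1	137.3	16	SHHLSLDRTNIPPKTFQKSSQLTELPQ	True
LR6	H-2-Kb	0.622	H/L	Zscan21	8	26.5	14	FSHSSNLTLHYRTLLVDRPYDCKCGKA	False
LR7	H-2-Kb	0.653	D/Y	Riok1	5	4.5	12	YLQVIQYMRKMYQYARLVHADLSEFNM	False
LR8	H-2-Kb	1	R/L	Extl1	9	40.4	12	VDFAFVVWQSFPELMVGFLSGSHFWDE	True
LR9	H-2-Kb	0.45	K/T	Nckap1	2	73.3	11	AVSHAGSMHRERRTFLRSALKELATVL	False
LR10	H-2-Kb	1	L/M	Plin2	1	280.2	9	MNSGVDNAITKSEMLVDQYFPLTQEEL	False
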