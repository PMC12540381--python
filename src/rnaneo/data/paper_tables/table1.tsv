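neoantigen_id	hla_allele	allele_frequency	amino_acid_change	gene_symbol	peptide_position	mut_mhc_ic50	priority_score	augmented_peptide	synthesis_failed	cross_ref
M1	H-2-Kd	0.836	H/Y	H2	2	461	83	VVVPLGKEQNYTCHVYHEGLPEPLTLRWEPP	False
M2	H-2-Kd	0.75	T/M	Atp10a	9	6482.9	72	GWRRPRRRRWEGRTRMVRSNLLPPLGTEDST	False
M3	H-2-Kd	0.8	Q/R	Rpl9	1	4030.4	68	CSHVQNMIKGVTLGFRYKMRSVYAHFPINVV	False
M4	H-2-Kd	0.8	S/F	Lyst	2	4081.7	64	AVLDVDGLDIQQELPFLSVGPSLHKQQASSD	False
M5	H-2-Kd	0.575	K/T	Zfr	7	4033.6	56	AYAAHIRGAKHQKVVTLHTKLGKPIPSTEPN	False
M6	H-2-Kd	0.558	R/W	Icmt	2	9856.8	55	MAGCAAWVPPGSEARLSLATFLLGASVLALP	True
M7	H-2-Dd	0.545	C/G	Scrn1	2	13181.7	53	AWLWGAEMGANEHGVGIANEAINAREPAAET	False
M8	H2-Ld	0.56	R/P	Lancl3	2	9614.6	52	LQMLLSYQEHLKPSDPELVWQSVDFLMEQEQ	True
M9	H-2-Kd	0.5	E/V	Eppk1	3	3266.8	49	GKATMEVKRGHLRGHVVPVWDILTSNYVSRD	False
M10	H2-Ld	0.909	T/I	Gm10093	4	9832.1	45	NYPLRDGIDDESYEAIFKPVMSKVMEMFQPS	False
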