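neoantigen_id	hla_allele	allele_frequency	amino_acid_change	gene_symbol	peptide_position	mut_mhc_ic50	priority_score	augmented_peptide	synthesis_failed	cross_ref
C1	H-2-Dd	1	P/L	Dtx2	8	1654.6	100	CLSRAPRPTGPPASRLASKSHSSVKRLRKMS	False
C2	H2-Ld	1	E/G	Sh3d21	6	12906.2	98	IPATEDTTLDKAGTPGSTLSGNKPAKDEALD	False
C3	H-2-Kd	0.778	R/W	Icmt	2	9856.8	77	MAGCAAWVPPGSEARLSLATFLLGASVLALP	False	M6
C4	H2-Ld	1	R/L	Dhx58	9	7777.9	75	LLETPRGKIQAKKWSLVPFSIPVFDILQDCT	False
C5	H-2-Kd	0.738	M/I	Polr2a	9	8697.4	56	VGALAAQSLGEPATQITLNTFHYAGVSAKNV	False
C6	H-2-Dd	0.563	C/G	Scrn1	2	13181.7	55	AWLWGAEMGANEHGVGIANEAINAREPAAET	False	M7
C7	H2-Ld	0.581	R/P	Lancl3	2	9614.6	54	LQMLLSYQEHLKPSDPELVWQSVDFLMEQEQ	False	M8
C8	H-2-Kd	0.502	K/T	Zfr	7	4033.6	49	AYAAHIRGAKHQKVVTLHTKLGKPIPSTEPN	False	M5
C9	H-2-Kd	0.465	H/Y	Wdr33	2	760.3	46	MATEIGSPPRFFYMPRFQHQAPRQLFYKRPD	False
C10	H2-Ld	0.562	D/G	Chd2	6	8635.9	43	RKPRVKKENKAPRLKGEHGLEPASPRHSDNP	True
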