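# rnaneo

Neoantigen identification from tumor **RNA sequencing alone**.

Personalized cancer vaccines target neoantigens — peptides created by somatic
mutations, absent from normal tissue, and presentable on the patient's MHC
molecules. The standard discovery workflow needs both whole-exome DNA
sequencing (for the mutations) and RNA-seq (for expression), which is costly
and slow. Because RNA-seq simultaneously carries the expressed somatic
variants, the gene-expression levels and the HLA type, a single RNA-seq run
of the tumor is enough to nominate vaccine candidates. `rnaneo` implements
that RNA-only pipeline as a reusable Python library plus a small CLI, for
computational immunologists and bioinformaticians building or evaluating
neoantigen pipelines.

## What it computes

Starting from a VCF of RNA-derived somatic calls, a transcript model
(FASTA + GFF3 CDS features), a gene-level TPM table and the typed MHC
alleles:

1. **Variant filtering** — the RNA-seq somatic cascade with inclusive
   thresholds: tumor DP ≥ 50×, normal DP ≥ 30×, tumor AD ≥ 5×, normal
   AD ≥ 3×, base quality ≥ Q20, strand odds ratio SOR ≤ 5.0, VAF ≥ 5 %,
   gene TPM ≥ 1. All eight rules are evaluated per variant (no
   short-circuit) so funnel reports are complete.
2. **Protein consequences** — codon-accurate annotation (missense,
   synonymous, stop-gain, frameshift, in-frame indel) on plus- and
   minus-strand, single- and multi-exon transcript models.
3. **Epitope enumeration** — every mutant 8–11-mer containing the altered
   residue, paired with its wild-type counterpart (38 pairs for an interior
   missense site; class II uses 15-mers).
4. **Binding prediction** — a pluggable predictor contract (IC50 nM,
   %rank): a deterministic built-in toy scorer, a precomputed-table adapter
   for exported NetMHCpan runs, or an external `netMHCpan` subprocess
   adapter. Conventional-mode candidates are gated at IC50 < 500 nM.
5. **Priority scoring** — `100 × Σ wᵢ sᵢ` over five bounded sub-scores:
   binding (log-scaled IC50 with a mutant/wild-type differential),
   expression (saturating TPM), VAF, DNA–RNA concordance, presentation
   (%rank). Top-N selection with deterministic tie-breaks.
6. **Vaccine design** — mutation-centred 27- or 31-residue long peptides
   (ALT residue at index 14 / 16; the window slides, never shrinks, at
   protein termini), plus synthesis-failure accounting.
7. **Set comparison** — RNA-only vs conventional candidate overlap at the
   variant or peptide level (counts, keys, Jaccard).

A fully seeded synthetic-cohort generator (`rnaneo.fixtures`) emits genome
FASTA, GFF3, VCF v4.2, TPM tables and a truth table of planted
consequences/filter failures, so the entire pipeline is testable offline.
The five published top-candidate tables (two mouse cell lines — 4T1 breast
and LLC lung — RNA-derived and conventional, plus one breast-cancer
patient) ship as checksummed TSV transcriptions.

## Worked example

Simulate a 20-gene, 40-variant cohort, then run the full pipeline against
the BALB/c class-I alleles:

```bash
rnaneo simulate --seed 42 --n-genes 20 --n-variants 40 --out cohort
printf 'H-2-Kd\nH-2-Dd\n' > alleles.txt
rnaneo run --vcf cohort/somatic.vcf --fasta cohort/genome.fa \
    --gff cohort/models.gff3 --expression cohort/expression.tsv \
    --alleles alleles.txt --top 5 --out top5.tsv
```

`top5.tsv` (abridged):

```
neoantigen_id  hla_allele  allele_frequency  amino_acid_change  gene_symbol  mut_mhc_ic50  priority_score  augmented_peptide
N1             H-2-Kd      0.709             C/W                GENE008      410.4         75.1            TQKLVFLSFSLPLIRTYATIEDYQWRSIKNP
N2             H-2-Kd      0.811             P/L                GENE018      1427.7        72.3            TDWYCRYLPLELQLFLYRYALTGPISLTYSN
N3             H-2-Kd      0.913             V/L                GENE017      4106.6        71.3            LFSLSAILGLQQVKELERSPGLNEKCAPLAQ
...
```

Each row is one mutation: its tumor allele fraction, amino-acid change, the
best-binding minimal epitope's predicted IC50 (toy predictor here — swap in
`--predictor table:binding.tsv` for real NetMHCpan output), the weighted
priority score in [0, 100], and the 31-mer vaccine peptide whose 16th
residue is the mutant amino acid. The filtering funnel for the same cohort:

```bash
rnaneo filter --vcf cohort/somatic.vcf --expression cohort/expression.tsv \
    --fasta cohort/genome.fa --gff cohort/models.gff3 \
    --normal-sample NORMAL --out verdicts.tsv --funnel funnel.tsv
# -> 27/40 variants pass   (funnel.tsv: TUMOR_DP 6, NORMAL_DP 4, TPM 7, ...)
```

Library use mirrors the CLI: `rnaneo.run_pipeline(...)` returns verdicts,
consequences and ranked `NeoantigenRecord`s; see `docs/methods.md` for the
model details.

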