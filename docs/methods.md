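# Methods

This note documents the models, defaults and design choices behind
`rnaneo`, and what the test suite does and does not demonstrate.

## Pipeline model

The package assumes somatic variant calling from tumor RNA-seq has already
happened (any caller emitting VCF v4.2 with per-sample `DP`/`AD`), and that
gene expression has been quantified to TPM. From there the pipeline is
deterministic: filter → annotate → enumerate epitopes → predict binding →
score → select → design long peptides.

### Variant filtering

Eight inclusive rules, all evaluated for every variant so that funnel
reports can attribute every failure:

| rule       | default | meaning                                   |
|------------|---------|-------------------------------------------|
| TUMOR_DP   | ≥ 50×   | tumor read depth                          |
| NORMAL_DP  | ≥ 30×   | matched-normal read depth                 |
| TUMOR_AD   | ≥ 5×    | tumor alt-supporting reads                |
| NORMAL_AD  | ≥ 3×    | normal allele depth (see below)           |
| BASEQ      | ≥ Q20   | site-level base quality                   |
| SOR        | ≤ 5.0   | strand odds ratio (strand-bias artifacts) |
| VAF        | ≥ 0.05  | tumor variant allele fraction (AD/DP)     |
| TPM        | ≥ 1     | expression of the host gene               |

Interpretation choices that the thresholds alone do not settle:

* **NORMAL_AD.** Requiring *alt* support in the normal would demand germline
  evidence inside a somatic filter, which is self-defeating. The default
  reads the rule as "the normal genotype is evaluable": reference-allele
  depth ≥ 3. A config switch (`normal_ad_interpretation="alt_at_most"`)
  instead rejects variants whose normal alt support exceeds the cutoff
  (germline-contamination guard).
* **Base quality** is taken from INFO `MBQ` (then `QA`), falling back to the
  record QUAL, with the source recorded on the variant; different callers
  emit different keys and none is universal. It is treated as a site-level
  summary, not per-read.
* **Missing annotations** (no SOR, no base quality, no normal sample) pass
  their rules vacuously rather than being coerced to 0; tumor-only mode
  (cell lines without a matched normal) skips the NORMAL_* rules and flags
  the run.
* **Expression** is joined at gene level via gene symbol, TPM units (the
  candidate tables report gene symbols and gene-level expression).

### Consequence annotation

Genomic coordinates are 1-based inclusive at the VCF/GFF3 boundary and
0-based half-open internally; the conversion lives entirely in
`formats_io`. Substitutions are classified by re-translating the edited
codon (standard nuclear code); minus-strand transcripts are edited in
genomic orientation and reverse-complemented. Indels whose length is not a
multiple of three are frameshifts; the mutant protein is re-translated from
the edit to the first novel stop. Multi-allelic sites are decomposed into
one record per ALT on read. When several transcripts carry the same
gene-level consequence, the longest transcript wins (one row per gene).

### Epitope enumeration

For a missense residue every window of length k ∈ {8, 9, 10, 11} covering
the altered position is emitted with its same-coordinate wild-type partner
— Σk = 38 pairs for an interior site, clipped (never padded) at the protein
termini. Frameshifts emit every k-mer overlapping the novel C-terminal
sequence with no wild-type partner; this is the standard neoantigen
treatment of novel open reading frames. Class II alleles use 15-mers, the
community convention for class-II core prediction; the length is
configurable.

### Binding prediction

External engines are deliberately behind an adapter contract
(`BindingResult`: IC50 in (0, 50000] nM, optional %rank, deterministic per
(peptide, allele, predictor)). Three implementations ship:

* **toy** — an allele-seeded residue-weight scorer for offline testing.
  The allele name is hashed (SHA-256) into a numpy `default_rng` seed; a
  peptide's score sums per-residue weights with the classical anchors
  (position 2 and the C-terminus) counted twice, then maps onto IC50 by a
  strictly decreasing logistic. This gives bit-identical results across
  runs and platforms, plausible anchor sensitivity, and is *not* a trained
  affinity model — absolute IC50s from it are meaningless.
* **table:path** — exact replay of a precomputed (peptide, allele, IC50,
  %rank) TSV, e.g. an exported NetMHCpan run; missing keys are errors,
  never imputations.
* **netmhcpan** — a subprocess adapter that raises
  `PredictorUnavailableError` when the binary is absent. There is no silent
  fallback between predictors.

Mutant and wild-type peptides of a pair are always scored by the same
predictor. Paired class-II alpha/beta names (e.g. `HLA-DPA10202-DPB10202`)
are passed to adapters combined, as typed.

### Priority score

Five sub-scores, each in [0, 1], combined as `100 × Σ wᵢ sᵢ` with weights
normalized to sum to 1 (defaults: equal):

* `s_binding = clamp(1 − ln IC50 / ln 50000)`; when the wild-type IC50 is
  known it is multiplied by `0.5 + clamp(log10(wt/mut), 0, 1)` and
  re-clamped, so mutant-specific binders outrank binders shared with the
  wild type.
* `s_expression = log1p(TPM) / (log1p(TPM) + log1p(h))`, half-saturation
  `h = 10` TPM — expression helps presentation but saturates; 10 TPM marks
  a solidly expressed gene.
* `s_vaf` = the tumor allele fraction (clonality proxy).
* `s_concordance` = 1 when a matched DNA call supports the variant; in
  RNA-only runs no DNA exists, so the dimension is neutral (1) and the run
  is flagged RNA-only.
* `s_presentation = 1 − %rank/100`, 0.5 when the predictor gives no rank.

The original study left its weight vector and transforms unpublished, so
the printed priority scores of the packaged candidate tables are **not** a
validation target anywhere in this package; only their magnitude (a 0–100
scale) is shared. Ranking ties break by lower mutant IC50, then higher TPM,
then gene symbol, making selection permutation-invariant.

Two cutoff policies coexist: *conventional* mode applies the strict
IC50 < 500 nM gate before ranking; *RNA* mode ranks without a hard gate
(the published RNA-derived top-10 lists contain candidates far above
500 nM, so a hard gate cannot be what that arm did).

### Long-peptide design

Vaccine peptides are 31-mers (4T1 / patient arms) or 27-mers (LLC arm),
with the mutant residue at 1-based index 16 resp. 14. Near a terminus the
window *slides* to keep full length rather than shrinking; only proteins
shorter than the window are returned whole and flagged truncated. The
centering rule is reconstructed from the published peptides themselves:
interior rows place the ALT residue exactly at 16/14, and the four
off-centre rows (Icmt R/W in the 4T1 table; three patient rows) are exactly
the slide-to-terminus pattern — each contains a single ALT occurrence, and
the N-terminal ones begin with the initiator methionine. Window choice
(31 vs 27) is per-run configuration, default 31.

## Synthetic cohorts

`fixtures.generate_cohort` emulates a deep bulk tumor RNA-seq experiment:
tumor depth ~ NegBin(mean 120, dispersion 5), normal depth mean 60, VAF ~
Beta(2, 2), TPM ~ LogNormal(1.5, 1.5²), 80 % missense / 10 % synonymous /
10 % frameshift, proteins of 80–200 aa on short single-exon contigs
(multi-exon and minus-strand models under config fractions, to exercise
splicing and strand code paths). All randomness flows from one seed;
output files are plain text with fixed formatting, so bundles are
byte-reproducible. With `planted_failures` the generator dedicates
variants to violating exactly one filter rule each while coercing the
background into safely passing ranges, making the truth table's pass/fail
partition exact by construction.

What the generator does **not** emulate: sequencing reads and their error
profiles, alignment and calling artifacts, germline contamination,
subclonal structure, splice/fusion/RNA-editing neoantigens, real codon
usage and real MHC binding. Passing the end-to-end tests therefore
demonstrates the pipeline's internal correctness (filtering logic,
coordinate arithmetic, translation, enumeration, scoring plumbing), not
predictive accuracy on real tumors — the latter depends on the external
binding predictor and the upstream caller.

## Numerical and procedural choices

* Thresholds compare inclusively on the stated side (≥ minima, ≤ SOR); the
  IC50 candidate gate is strictly `<` 500 nM.
* VAF is recomputed as AD/DP on read and the stored value must agree to
  1e-6; a variant with DP = 0 has undefined VAF and fails depth anyway.
* Toy-predictor IC50 is clamped away from 0 at 1e-6 nM to preserve the
  open interval contract.
* Problem sizes in the tests and the acceptance script (cohorts of 40–100
  variants over 20–30 genes, 500-variant oracle comparisons, 200-case
  property sweeps) were chosen as the smallest sizes that exercise every
  rule and code path several times over.
* Candidate-table transcriptions are pinned by SHA-256; any edit fails the
  suite. The patient table prints no per-row synthesis-failure markers
  (the study reports 6 of 9 synthesized without naming them), so its rows
  all carry `synthesis_failed=False` and per-arm synthesized counts are
  asserted only for the four mouse tables.

## Known limitations

* Frameshift consequences are filtered, annotated and enumerated, but the
  final vaccine-candidate records are built from missense/in-frame
  consequences only (a mutation-centred long peptide is not defined for a
  novel reading frame; windows over the novel tail would need a separate
  design rule).
* The DNA–RNA concordance dimension is structurally neutral in RNA-only
  runs; it only discriminates when a DNA callset is supplied.
* seq2HLA-style genotype parsing accepts the two-column (locus, 4-digit
  allele) dialect and plain allele lists; other HLA-typing output formats
  need conversion.
* No proteasomal-processing or immunogenicity model is included; %rank is
  the only presentation proxy.
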