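"""End-to-end orchestration: VCF in, ranked vaccine candidates out.

Glues the stages together in method order: read inputs → filter variants →
map to protein consequences → enumerate minimal epitopes → score binding for
every typed MHC allele → take each variant's best epitope → priority-score,
rank, select the top N → design the long peptide for each selected
candidate.  The library modules stay independently usable; this is the path
the command-line interface and the end-to-end tests run.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import binding as binding_mod
from .binding import BindingPredictor, get_predictor
from .consequence_peptides import (CLASS_I_LENGTHS, CLASS_II_LENGTH,
                                   ProteinConsequence, annotate_variant,
                                   deduplicate_consequences, design_long_peptide,
                                   enumerate_epitopes, variant_key)
from .formats_io import (MhcAllele, NeoantigenRecord, SomaticVariant,
                         TranscriptModel, read_expression,
                         read_transcript_models, read_vcf)
from .prioritization import (ScoringWeights, priority_score, rank_and_select,
                             subscores)
from .variant_filtering import FilterThresholds, FilterVerdict, apply_filters


@dataclass
class PipelineResult:
    variants: list[SomaticVariant]
    verdicts: list[FilterVerdict]
    consequences: list[ProteinConsequence]
    candidates: list[NeoantigenRecord]      # all scored candidates, ranked
    selected: list[NeoantigenRecord]        # top-N
    tumor_only: bool


def _gene_lookup(models: Sequence[TranscriptModel]):
    """Map a variant to the symbol of a transcript whose CDS contains it."""
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)

    def lookup(v: SomaticVariant) -> str | None:
        for m in by_chrom.get(v.chrom, ()):
            if m.genomic_to_cds(v.pos) is not None:
                return m.gene_symbol
        return None

    return lookup


def _models_for(models: Sequence[TranscriptModel],
                v: SomaticVariant) -> list[TranscriptModel]:
    return [m for m in models
            if m.chrom == v.chrom and m.genomic_to_cds(v.pos) is not None]


def run_pipeline(vcf: str | Path,
                 fasta: str | Path,
                 gff3: str | Path,
                 expression: str | Path,
                 alleles: Sequence[MhcAllele],
                 tumor_sample: str = "TUMOR",
                 normal_sample: str | None = "NORMAL",
                 predictor: BindingPredictor | str = "toy",
                 thresholds: FilterThresholds = FilterThresholds(),
                 weights: ScoringWeights = ScoringWeights(),
                 mode: str = "rna",
                 window: int = 31,
                 top_n: int = 10,
                 class_i_lengths=CLASS_I_LENGTHS) -> PipelineResult:
    """Run the full candidate-identification pipeline on one sample.

    ``mode="conventional"`` applies the strict IC50 < 500 nM candidate gate
    before ranking; ``mode="rna"`` ranks every passing epitope by priority
    score without the gate.  Candidate records are built from missense and
    in-frame consequences (the ones a mutation-centred long peptide is
    defined for).
    """
    if mode not in ("rna", "conventional"):
        raise ValueError(f"mode must be 'rna' or 'conventional', got {mode!r}")
    if isinstance(predictor, str):
        predictor = get_predictor(predictor)

    variants = read_vcf(vcf, tumor_sample=tumor_sample,
                        normal_sample=normal_sample)
    expr = read_expression(expression)
    models = read_transcript_models(fasta, gff3)
    tumor_only = normal_sample is None

    verdicts = apply_filters(variants, expr, _gene_lookup(models),
                             thresholds, tumor_only=tumor_only)
    passed_keys = {v.variant_key for v in verdicts if v.passed}

    tpm_by_symbol = dict(zip(expr["gene_symbol"], expr["tpm"]))
    vaf_by_key = {v.key(): (v.vaf if v.vaf is not None else 0.0)
                  for v in variants}

    consequences: list[ProteinConsequence] = []
    conseq_vaf: dict[str, float] = {}
    for v in variants:
        if v.key() not in passed_keys:
            continue
        for model in _models_for(models, v):
            c = annotate_variant(v, model)
            if c and c.consequence_class not in ("synonymous", "stop_gain"):
                consequences.append(c)
                conseq_vaf[variant_key(c)] = vaf_by_key[v.key()]
    consequences = deduplicate_consequences(consequences)

    candidates: list[NeoantigenRecord] = []
    for c in consequences:
        if c.consequence_class not in ("missense", "inframe_indel"):
            continue
        best = None  # (ic50, result, wt_result, peptide_position)
        for allele in alleles:
            lengths = (class_i_lengths if allele.mhc_class == "I"
                       else {CLASS_II_LENGTH})
            for mut_pep, wt_pep, pep_pos in enumerate_epitopes(c, lengths):
                res = predictor.predict([mut_pep], allele)[0]
                if best is None or res.ic50 < best[0]:
                    wt_res = (predictor.predict([wt_pep], allele)[0]
                              if wt_pep is not None else None)
                    best = (res.ic50, res, wt_res, pep_pos)
        if best is None:
            continue
        ic50, res, wt_res, pep_pos = best
        if mode == "conventional" and not binding_mod.candidate_cutoff([res]):
            continue
        tpm = float(tpm_by_symbol.get(c.gene_symbol, 0.0))
        vaf = conseq_vaf[variant_key(c)]
        sub = subscores(mut_ic50=ic50, tpm=tpm, vaf=vaf,
                        wt_ic50=wt_res.ic50 if wt_res else None,
                        concordant=None, percent_rank=res.percent_rank)
        score = priority_score(sub, weights)
        peptide, mut_idx, truncated = design_long_peptide(c, window=window)
        candidates.append(NeoantigenRecord(
            neoantigen_id="",  # assigned after ranking
            allele=res.allele, allele_frequency=vaf, aa_change=c.aa_change,
            gene_symbol=c.gene_symbol, peptide_position=pep_pos,
            mut_ic50=ic50, wt_ic50=wt_res.ic50 if wt_res else None,
            tpm=tpm, priority_score=score, augmented_peptide=peptide,
            truncated=truncated))

    from dataclasses import replace
    ranked = rank_and_select(candidates, n=max(len(candidates), 1)) \
        if candidates else []
    ranked = [replace(r, neoantigen_id=f"N{i + 1}")
              for i, r in enumerate(ranked)]
    selected = rank_and_select(ranked, n=top_n) if ranked else []
    return PipelineResult(variants=variants, verdicts=verdicts,
                          consequences=consequences, candidates=ranked,
                          selected=selected, tumor_only=tumor_only)
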