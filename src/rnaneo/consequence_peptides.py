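"""Protein consequences, minimal epitopes and long vaccine peptides.

A filtered variant is projected onto a transcript model to obtain its protein
consequence (missense, synonymous, stop-gain, frameshift or in-frame indel);
nonsynonymous consequences are expanded into every mutant 8–11-mer containing
the altered residue, each paired with its same-length wild-type counterpart;
and the mutation-centred 27- or 31-residue long peptide used for vaccine
synthesis is designed around the altered residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .formats_io import (SomaticVariant, TranscriptModel, ValidationError,
                         translate_cds)

CLASS_I_LENGTHS = frozenset({8, 9, 10, 11})
#: Default class-II prediction length (community convention for 15-mer cores).
CLASS_II_LENGTH = 15


@dataclass(frozen=True)
class ProteinConsequence:
    """A variant mapped onto a protein.

    For frameshifts ``mutant_protein`` runs to the first novel stop codon and
    ``alt_aa`` is undefined; for missense the mutant protein differs from the
    wild type at exactly ``aa_pos``.
    """

    gene_symbol: str
    transcript_id: str
    aa_pos: int                    # 1-based residue index of first change
    ref_aa: str
    alt_aa: str | None
    consequence_class: str         # missense | frameshift | inframe_indel |
                                   # stop_gain | synonymous
    mutant_protein: str
    wildtype_protein: str

    @property
    def aa_change(self) -> str:
        alt = self.alt_aa if self.alt_aa is not None else "fs"
        return f"{self.ref_aa}/{alt}"


class NoConsequence:
    """Sentinel for a variant falling outside the transcript's CDS."""

    def __bool__(self):
        return False

    def __repr__(self):  # pragma: no cover
        return "NoConsequence()"


NO_CONSEQUENCE = NoConsequence()


def annotate_variant(variant: SomaticVariant,
                     model: TranscriptModel) -> ProteinConsequence | NoConsequence:
    """Project a variant onto a transcript model, codon-accurately.

    Substitutions are classified by comparing the reference and mutant codon
    translations (missense / synonymous / stop-gain); indels whose length is
    not a multiple of three shift the reading frame and the mutant protein is
    re-translated from the edit to the first stop.  Minus-strand transcripts
    are handled by editing the genome-orientation CDS before reverse
    complementing.
    """
    cds_offset = model.genomic_to_cds(variant.pos)
    if cds_offset is None:
        return NO_CONSEQUENCE

    # Apply the edit in CDS orientation.
    ref, alt = variant.ref_allele, variant.alt_allele
    if model.strand == "-":
        ref = str(Seq(ref).reverse_complement())
        alt = str(Seq(alt).reverse_complement())
        # For a multi-base REF on the minus strand the VCF anchors the left
        # end; in CDS orientation the edit starts at the right end.
        cds_offset = cds_offset - (len(ref) - 1)
        if cds_offset < 0:
            return NO_CONSEQUENCE
    cds = model.cds_seq
    if cds[cds_offset:cds_offset + len(ref)] != ref:
        raise ValidationError(
            f"{model.transcript_id}: REF allele {variant.ref_allele!r} does "
            f"not match CDS at {variant.key()}")
    mutant_cds = cds[:cds_offset] + alt + cds[cds_offset + len(ref):]

    wt_protein = model.protein_seq
    indel_len = len(alt) - len(ref)

    if indel_len == 0:
        mut_protein = translate_cds(mutant_cds, to_first_stop=True)
        aa_pos = cds_offset // 3 + 1
        if aa_pos > len(wt_protein):
            return NO_CONSEQUENCE  # edit in the stop codon only
        ref_aa = wt_protein[aa_pos - 1]
        alt_codon = mutant_cds[(aa_pos - 1) * 3: aa_pos * 3]
        alt_aa = str(Seq(alt_codon).translate())
        if alt_aa == "*":
            return ProteinConsequence(
                gene_symbol=model.gene_symbol, transcript_id=model.transcript_id,
                aa_pos=aa_pos, ref_aa=ref_aa, alt_aa=None,
                consequence_class="stop_gain", mutant_protein=mut_protein,
                wildtype_protein=wt_protein)
        cls = "synonymous" if alt_aa == ref_aa else "missense"
        return ProteinConsequence(
            gene_symbol=model.gene_symbol, transcript_id=model.transcript_id,
            aa_pos=aa_pos, ref_aa=ref_aa, alt_aa=alt_aa,
            consequence_class=cls, mutant_protein=mut_protein,
            wildtype_protein=wt_protein)

    # Indel: first affected codon is the one containing the first changed base
    # (the VCF anchor base itself is unchanged).
    first_changed = cds_offset + 1
    aa_pos = min(first_changed // 3 + 1, len(wt_protein))
    mut_protein = translate_cds(mutant_cds, to_first_stop=True)
    ref_aa = wt_protein[aa_pos - 1]
    if indel_len % 3 != 0:
        return ProteinConsequence(
            gene_symbol=model.gene_symbol, transcript_id=model.transcript_id,
            aa_pos=aa_pos, ref_aa=ref_aa, alt_aa=None,
            consequence_class="frameshift", mutant_protein=mut_protein,
            wildtype_protein=wt_protein)
    return ProteinConsequence(
        gene_symbol=model.gene_symbol, transcript_id=model.transcript_id,
        aa_pos=aa_pos, ref_aa=ref_aa, alt_aa=None,
        consequence_class="inframe_indel", mutant_protein=mut_protein,
        wildtype_protein=wt_protein)


def enumerate_epitopes(consequence: ProteinConsequence,
                       lengths: Iterable[int] = CLASS_I_LENGTHS,
                       ) -> list[tuple[str, str | None, int]]:
    """All mutant k-mers containing altered sequence, with wild-type partners.

    For a missense consequence every window of each length k that covers the
    mutated residue is emitted (clipped at the protein termini), paired with
    the same-coordinate wild-type window; an interior residue therefore yields
    Σk windows (38 for k ∈ {8,9,10,11}).  For frameshifts every k-mer
    overlapping the novel C-terminal sequence is emitted with no wild-type
    partner.  Synonymous and stop-gain consequences yield nothing.

    Returns ``(mut_peptide, wt_peptide, peptide_position)`` triples where
    ``peptide_position`` is the 1-based index of the (first) mutated residue
    within the peptide.
    """
    if consequence.consequence_class in ("synonymous", "stop_gain"):
        return []

    mut = consequence.mutant_protein
    out: list[tuple[str, str | None, int]] = []
    seen: set[tuple[str, int]] = set()

    if consequence.consequence_class == "missense":
        wt = consequence.wildtype_protein
        pos0 = consequence.aa_pos - 1
        for k in sorted(lengths):
            lo = max(0, pos0 - k + 1)
            hi = min(pos0, len(mut) - k)
            for start in range(lo, hi + 1):
                pair = (mut[start:start + k], pos0 - start + 1)
                if pair in seen:
                    continue
                seen.add(pair)
                out.append((mut[start:start + k], wt[start:start + k],
                            pos0 - start + 1))
        return out

    # Frameshift / in-frame indel: novel sequence starts at aa_pos and, for a
    # frameshift, runs to the (new) C-terminus.
    novel_start0 = consequence.aa_pos - 1
    for k in sorted(lengths):
        lo = max(0, novel_start0 - k + 1)
        for start in range(lo, max(lo, len(mut) - k) + 1):
            if start + k > len(mut):
                continue
            first_novel = max(novel_start0 - start + 1, 1)
            pair = (mut[start:start + k], first_novel)
            if pair in seen:
                continue
            seen.add(pair)
            out.append((mut[start:start + k], None, first_novel))
    return out


def design_long_peptide(consequence: ProteinConsequence,
                        window: int = 31) -> tuple[str, int, bool]:
    """Design the mutation-centred long peptide used for vaccine synthesis.

    The altered residue is centred: 1-based index 16 in a 31-mer, 14 in a
    27-mer.  Near a terminus the window slides (keeping its full length)
    rather than shrinking; only a protein shorter than the window is returned
    whole, flagged truncated.

    Returns ``(peptide, mutation_index, truncated)`` with a 1-based
    ``mutation_index`` pointing at the altered residue.
    """
    if window not in (27, 31):
        raise ValidationError(f"long-peptide window must be 27 or 31, got {window}")
    if consequence.consequence_class not in ("missense", "inframe_indel"):
        raise ValidationError(
            "long-peptide design needs a missense or in-frame consequence, "
            f"got {consequence.consequence_class}")
    protein = consequence.mutant_protein
    if len(protein) < 8:
        raise ValidationError(
            f"protein of length {len(protein)} too short for peptide design")
    pos0 = consequence.aa_pos - 1
    if pos0 >= len(protein):
        raise ValidationError("mutated residue falls outside the mutant protein")

    if len(protein) < window:
        return protein, consequence.aa_pos, True

    center0 = window // 2  # 0-based: 15 for 31-mer, 13 for 27-mer
    start = pos0 - center0
    start = max(0, min(start, len(protein) - window))
    return protein[start:start + window], pos0 - start + 1, False


def variant_key(consequence: ProteinConsequence) -> str:
    """Canonical gene-level key ``GENE:aa_pos:REF/ALT`` for set comparison."""
    return (f"{consequence.gene_symbol.upper()}:{consequence.aa_pos}:"
            f"{consequence.aa_change.upper()}")


def deduplicate_consequences(consequences: Sequence[ProteinConsequence],
                             ) -> list[ProteinConsequence]:
    """Keep one consequence per gene-level key, preferring the longest
    transcript (Tables report one row per gene)."""
    best: dict[str, ProteinConsequence] = {}
    for c in consequences:
        key = variant_key(c)
        prev = best.get(key)
        if prev is None or len(c.wildtype_protein) > len(prev.wildtype_protein):
            best[key] = c
    return list(best.values())
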