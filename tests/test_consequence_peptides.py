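import numpy as np
import pytest
from Bio.Seq import Seq

from rnaneo.consequence_peptides import (NO_CONSEQUENCE, ProteinConsequence,
                                         annotate_variant,
                                         deduplicate_consequences,
                                         design_long_peptide,
                                         enumerate_epitopes, variant_key)
from rnaneo.fixtures import load_paper_tables
from rnaneo.formats_io import (SomaticVariant, TranscriptModel,
                               ValidationError, translate_cds)

AAS = "ACDEFGHIKLMNPQRSTVWY"


def toy_model(cds, chrom="c", strand="+", start=101):
    """Single-exon model whose CDS begins at genomic `start`."""
    genomic = cds if strand == "+" else str(Seq(cds).reverse_complement())
    return TranscriptModel(
        transcript_id="tx1", gene_symbol="G1", chrom=chrom, strand=strand,
        cds_intervals=((start, start + len(cds) - 1),),
        cds_seq=cds, protein_seq=translate_cds(cds))


def snv(pos, ref, alt, **kw):
    defaults = dict(chrom="c", pos=pos, ref_allele=ref, alt_allele=alt,
                    variant_class="SNV", tumor_dp=60, tumor_ad_alt=6)
    defaults.update(kw)
    return SomaticVariant(**defaults)


def cds_with_codon(codon, at_residue, n_aa=30):
    """ATG + filler codons with `codon` at 1-based residue `at_residue`."""
    filler = "GCT"  # Ala
    codons = ["ATG"] + [filler] * (n_aa - 1) + ["TAA"]
    codons[at_residue - 1] = codon
    return "".join(codons)


class TestAnnotateVariant:
    def test_cat_to_tat_is_missense_h_to_y(self):
        cds = cds_with_codon("CAT", 14)
        model = toy_model(cds)
        # CAT codon starts at CDS offset 39 -> genomic 101+39=140
        c = annotate_variant(snv(140, "C", "T"), model)
        assert c.consequence_class == "missense"
        assert (c.ref_aa, c.alt_aa, c.aa_pos) == ("H", "Y", 14)
        assert c.aa_change == "H/Y"
        assert c.mutant_protein[13] == "Y"
        diffs = [i for i, (a, b) in
                 enumerate(zip(c.mutant_protein, c.wildtype_protein)) if a != b]
        assert diffs == [13]

    def test_third_position_wobble_is_synonymous(self):
        cds = cds_with_codon("CTA", 10)  # Leu; CTA->CTG still Leu
        model = toy_model(cds)
        c = annotate_variant(snv(101 + 27 + 2, "A", "G"), model)
        assert c.consequence_class == "synonymous"

    def test_stop_gain_detected(self):
        cds = cds_with_codon("TAC", 10)  # Tyr; TAC->TAA stop
        model = toy_model(cds)
        c = annotate_variant(snv(101 + 27 + 2, "C", "A"), model)
        assert c.consequence_class == "stop_gain"
        assert len(c.mutant_protein) == 9

    def test_single_base_deletion_is_frameshift_translated_to_stop(self):
        rng = np.random.default_rng(1)
        cds = cds_with_codon("CAT", 10, n_aa=40)
        model = toy_model(cds)
        # delete first base of codon 10: anchor at last base of codon 9
        anchor_offset = 9 * 3 - 1
        anchor_base = cds[anchor_offset]
        var = SomaticVariant("c", 101 + anchor_offset,
                             anchor_base + cds[anchor_offset + 1], anchor_base,
                             "deletion", tumor_dp=60, tumor_ad_alt=6)
        c = annotate_variant(var, model)
        assert c.consequence_class == "frameshift"
        assert c.aa_pos == 10
        # independent re-translation of the shifted CDS
        mutant_cds = cds[:anchor_offset + 1] + cds[anchor_offset + 2:]
        assert c.mutant_protein == translate_cds(mutant_cds, to_first_stop=True)

    def test_reverse_strand_handled_by_reverse_complement(self):
        cds = cds_with_codon("CAT", 14)
        model = toy_model(cds, strand="-")
        # CDS offset of the C in CAT is 39; genomic pos on minus strand:
        # contig holds revcomp(cds), so offset o maps to start+len-1-o
        pos = 101 + len(cds) - 1 - 39
        c = annotate_variant(snv(pos, "G", "A"), model)  # revcomp(C->T)
        assert c.consequence_class == "missense"
        assert (c.ref_aa, c.alt_aa, c.aa_pos) == ("H", "Y", 14)

    def test_variant_outside_cds_yields_no_consequence(self):
        model = toy_model(cds_with_codon("CAT", 5))
        assert annotate_variant(snv(5, "A", "G"), model) is NO_CONSEQUENCE

    def test_ref_mismatch_is_model_validation_error(self):
        model = toy_model(cds_with_codon("CAT", 14))
        with pytest.raises(ValidationError):
            annotate_variant(snv(140, "G", "T"), model)

    def test_translation_fidelity_on_random_fixtures(self):
        """Annotation agrees with independent re-translation, 500 cases."""
        rng = np.random.default_rng(7)
        sense = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in ("TAA", "TAG", "TGA")]
        for _ in range(500):
            n_aa = int(rng.integers(20, 60))
            codons = ["ATG"] + [sense[i] for i in
                                rng.integers(0, len(sense), n_aa - 1)] + ["TAA"]
            cds = "".join(codons)
            model = toy_model(cds)
            off = int(rng.integers(3, 3 * n_aa))
            ref = cds[off]
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == ref:
                continue
            c = annotate_variant(snv(101 + off, ref, alt), model)
            mutant_cds = cds[:off] + alt + cds[off + 1:]
            expected = translate_cds(mutant_cds, to_first_stop=True)
            if c is NO_CONSEQUENCE:
                continue
            assert c.mutant_protein == expected


def missense(aa_pos, protein_len=100, alt="Y", ref="H"):
    wt = "".join("ACDEFGIKLMNPQRSTVW"[i % 18] for i in range(protein_len))
    wt = wt[:aa_pos - 1] + ref + wt[aa_pos:]
    mut = wt[:aa_pos - 1] + alt + wt[aa_pos:]
    return ProteinConsequence("G1", "tx1", aa_pos, ref, alt, "missense",
                              mut, wt)


class TestEnumerateEpitopes:
    def test_interior_missense_yields_38_pairs(self):
        pairs = enumerate_epitopes(missense(50))
        assert len(pairs) == 8 + 9 + 10 + 11 == 38

    def test_n_terminal_missense_yields_one_per_length(self):
        pairs = enumerate_epitopes(missense(1, ref="M", alt="V"))
        assert len(pairs) == 4
        assert all(pos == 1 for _, _, pos in pairs)
        assert sorted(len(p) for p, _, _ in pairs) == [8, 9, 10, 11]

    def test_synonymous_yields_nothing(self):
        c = ProteinConsequence("G1", "tx1", 5, "A", "A", "synonymous",
                               "A" * 50, "A" * 50)
        assert enumerate_epitopes(c) == []

    def test_counts_match_brute_force_near_termini(self):
        """Clipped window counts equal brute-force enumeration, 200 cases."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(8, 60))
            pos = int(rng.integers(1, n + 1))
            c = missense(pos, protein_len=n)
            got = enumerate_epitopes(c)
            brute = set()
            for k in (8, 9, 10, 11):
                for start in range(0, n - k + 1):
                    if start <= pos - 1 <= start + k - 1:
                        brute.add((c.mutant_protein[start:start + k],
                                   pos - start))
            assert {(p, i) for p, _, i in got} == brute

    def test_mut_and_wt_differ_only_at_peptide_position(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = int(rng.integers(12, 80))
            pos = int(rng.integers(1, n + 1))
            c = missense(pos, protein_len=n)
            for mut_pep, wt_pep, ppos in enumerate_epitopes(c):
                diffs = [i for i, (a, b) in enumerate(zip(mut_pep, wt_pep))
                         if a != b]
                assert diffs == [ppos - 1]
                assert mut_pep[ppos - 1] == "Y"

    def test_frameshift_emits_novel_kmers_without_wt(self):
        mut = "M" + "A" * 20 + "WLRTK"  # novel tail from residue 22
        c = ProteinConsequence("G1", "tx1", 22, "G", None, "frameshift",
                               mut, "M" + "A" * 40)
        pairs = enumerate_epitopes(c)
        assert pairs and all(wt is None for _, wt, _ in pairs)
        assert all("W" in p or pos <= 8 for p, _, pos in pairs)


class TestDesignLongPeptide:
    @pytest.mark.parametrize("window,center", [(31, 16), (27, 14)])
    def test_interior_mutation_is_centred(self, window, center):
        pep, idx, truncated = design_long_peptide(missense(50), window)
        assert len(pep) == window and not truncated
        assert idx == center
        assert pep[idx - 1] == "Y"

    @pytest.mark.parametrize("table_id,window", [(1, 31), (3, 27), (5, 31)])
    def test_published_rows_reproducible_by_the_designer(self, table_id,
                                                         window):
        """Every published augmented peptide is reproduced exactly by the
        mutation-centred designer: interior mutations sit at index 16
        (31-mers) / 14 (27-mers); the few terminal rows (e.g. the Icmt R/W
        peptide starting at the initiator Met) match the slide-to-boundary
        rule with the ALT residue off-centre."""
        center = 16 if window == 31 else 14
        for rec in load_paper_tables(table_id):
            alt = rec.aa_change.split("/")[1]
            peptide = rec.augmented_peptide
            if peptide[center - 1] == alt:
                idx = center
                protein, aa_pos = peptide, center  # interior: identity window
            else:
                hits = [i + 1 for i, ch in enumerate(peptide) if ch == alt]
                assert len(hits) == 1, rec.neoantigen_id
                idx = hits[0]
                if idx < center:   # peptide flush with the N-terminus
                    protein, aa_pos = peptide + "A" * 20, idx
                else:              # flush with the C-terminus
                    protein, aa_pos = "A" * 20 + peptide, 20 + idx
            ref = rec.aa_change.split("/")[0]
            wt = protein[:aa_pos - 1] + ref + protein[aa_pos:]
            c = ProteinConsequence(rec.gene_symbol, "tx", aa_pos, ref, alt,
                                   "missense", protein, wt)
            pep, got_idx, truncated = design_long_peptide(c, window)
            assert pep == peptide and not truncated
            assert got_idx == idx and pep[got_idx - 1] == alt

    def test_near_terminus_window_slides_not_shrinks(self):
        pep, idx, truncated = design_long_peptide(missense(5), 31)
        assert len(pep) == 31 and not truncated
        assert idx == 5 and pep[4] == "Y"
        pep, idx, truncated = design_long_peptide(missense(98), 31)
        assert len(pep) == 31 and not truncated
        assert pep[idx - 1] == "Y"

    def test_short_protein_returned_whole_and_flagged(self):
        pep, idx, truncated = design_long_peptide(
            missense(10, protein_len=20), 31)
        assert truncated and len(pep) == 20 and pep[idx - 1] == "Y"

    def test_slide_matches_brute_force(self):
        """Sliding keeps the full window and the mutant residue as close to
        centre as the terminus allows."""
        for pos in range(1, 101):
            pep, idx, truncated = design_long_peptide(
                missense(pos, protein_len=100), 31)
            assert not truncated and len(pep) == 31
            assert pep[idx - 1] == "Y"
            starts = [s for s in range(0, 70) if s <= pos - 1 <= s + 30]
            best = min(starts, key=lambda s: abs((pos - 1 - s) - 15))
            assert idx - 1 == pos - 1 - best

    def test_window_must_be_27_or_31(self):
        with pytest.raises(ValidationError):
            design_long_peptide(missense(50), 29)


class TestVariantKey:
    def test_canonical_form(self):
        assert variant_key(missense(14)) == "G1:14:H/Y"

    def test_same_consequence_via_two_transcripts_same_key(self):
        a = missense(14)
        b = ProteinConsequence("g1", "tx2", 14, "H", "Y", "missense",
                               a.mutant_protein, a.wildtype_protein)
        assert variant_key(a) == variant_key(b)

    def test_keys_unique_iff_gene_pos_change_unique(self):
        rng = np.random.default_rng(5)
        seen = {}
        for _ in range(100):
            gene = f"G{int(rng.integers(0, 10))}"
            pos = int(rng.integers(1, 30))
            alt = AAS[int(rng.integers(0, 20))]
            if alt == "H":
                continue
            c = ProteinConsequence(gene, "tx", pos, "H", alt, "missense",
                                   "A" * 40, "A" * 40)
            key = variant_key(c)
            ident = (gene.upper(), pos, "H", alt)
            if key in seen:
                assert seen[key] == ident
            seen[key] = ident

    def test_dedup_keeps_longest_transcript(self):
        short = missense(14, protein_len=50)
        long = missense(14, protein_len=90)
        kept = deduplicate_consequences([short, long])
        assert kept == [long]
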