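"""Synthetic cohorts and packaged published candidate tables.

The generator emits a complete miniature study — genome FASTA, GFF3
transcript models, a VCF v4.2 of somatic calls with tumor/normal DP/AD and
site-level SOR / base-quality annotations, a gene-level TPM table — plus a
truth table recording every planted consequence and its expected pass/fail
verdict per filter rule, so the whole pipeline can be exercised and checked
offline.  All randomness flows from one seed through one generator, and all
files are emitted as plain text with fixed float formatting, so a given seed
reproduces the bundle byte for byte.

Separately, :func:`load_paper_tables` loads the five packaged candidate
tables (two mouse cell lines, RNA-derived and conventional, plus one human
breast-cancer patient) that ship with the package as TSV transcriptions;
their checksums are pinned against silent edits.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .formats_io import NeoantigenRecord, ValidationError, parse_allele

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"

PLANTABLE_RULES = ("TUMOR_DP", "NORMAL_DP", "TUMOR_AD", "NORMAL_AD",
                   "BASEQ", "SOR", "VAF", "TPM")

#: sha256 of the packaged table transcriptions; any edit fails the suite.
PAPER_TABLE_CHECKSUMS = {
    1: "641145f94e749f919f258998582bee60dc5ac0d48baecd6ae07c59b4de94e58c",
    2: "2d8aba5dd06308205f1f6bada4c7720a672be4b02905eb5adc6a729f1e2c7df0",
    3: "f25bab27cdcb2ce859a16323e9500020b7620150dc6395016bc50ce5cbea6ebe",
    4: "a1e2c563d54302c1b6fabf67c5e61956644a5cfbd50569a78e7cfe45a2524f3c",
    5: "1f58009109c83f9da7de4a12c9af637505a9fce5d8fb1655706ef073e63e14b0",
}


@dataclass(frozen=True)
class CohortConfig:
    """Statistical shape of a synthetic cohort.

    Defaults mirror a deep bulk tumor RNA-seq experiment: tumor coverage
    negative-binomially distributed around 120× (so the 50× floor is usually
    but not always met), clonal-to-subclonal VAFs from Beta(2, 2), log-normal
    gene expression around a few TPM, and a mostly-missense mutation
    spectrum.
    """

    n_genes: int = 60
    n_variants: int = 120
    vaf_alpha: float = 2.0
    vaf_beta: float = 2.0
    dp_mean: float = 120.0
    dp_dispersion: float = 5.0
    normal_dp_mean: float = 60.0
    tpm_log_mean: float = 1.5
    tpm_log_sigma: float = 1.5
    fraction_missense: float = 0.8
    fraction_synonymous: float = 0.1
    fraction_frameshift: float = 0.1
    protein_len_min: int = 80
    protein_len_max: int = 200
    multi_exon_fraction: float = 0.0
    reverse_strand_fraction: float = 0.0
    flank: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_variants <= 0:
            raise ValidationError("n_genes and n_variants must be > 0")
        fracs = (self.fraction_missense, self.fraction_synonymous,
                 self.fraction_frameshift)
        if any(not 0 <= f <= 1 for f in fracs) or abs(sum(fracs) - 1) > 1e-9:
            raise ValidationError("consequence fractions must sum to 1")


@dataclass
class CohortBundle:
    """Paths of one generated cohort plus its in-memory truth table."""

    directory: Path
    fasta: Path
    gff3: Path
    vcf: Path
    expression: Path
    truth: pd.DataFrame
    tumor_sample: str = "TUMOR"
    normal_sample: str = "NORMAL"


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial parameterised by mean and dispersion (size)."""
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _random_cds(rng: np.random.Generator, n_aa: int) -> str:
    """ATG + random non-stop codons + one stop codon."""
    all_codons = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
    sense = [c for c in all_codons if c not in _STOP_CODONS and c != "ATG"]
    codons = ["ATG"]
    codons += [sense[i] for i in rng.integers(0, len(sense), size=n_aa - 1)]
    codons.append(sorted(_STOP_CODONS)[int(rng.integers(0, 3))])
    return "".join(codons)


def _pick_substitution(rng: np.random.Generator, cds: str, aa_pos: int,
                       want_missense: bool) -> tuple[int, str, str] | None:
    """A single-base change in codon ``aa_pos``; missense or synonymous.

    Returns (0-based cds offset, ref base, alt base) or None when the codon
    admits no such substitution.
    """
    codon = cds[(aa_pos - 1) * 3: aa_pos * 3]
    ref_aa = str(Seq(codon).translate())
    options = []
    for within in range(3):
        for alt_base in _BASES:
            if alt_base == codon[within]:
                continue
            alt_codon = codon[:within] + alt_base + codon[within + 1:]
            if alt_codon in _STOP_CODONS:
                continue
            changed = str(Seq(alt_codon).translate()) != ref_aa
            if changed == want_missense:
                options.append(((aa_pos - 1) * 3 + within,
                                codon[within], alt_base))
    if not options:
        return None
    return options[int(rng.integers(0, len(options)))]


# Straight-line truth rules: deliberately independent of variant_filtering.
_DEFAULTS = dict(tumor_dp_min=50, normal_dp_min=30, tumor_ad_min=5,
                 normal_ad_min=3, base_quality_min=20.0, sor_max=5.0,
                 vaf_min=0.05, tpm_min=1.0)


def _truth_failed_rules(tumor_dp, tumor_ad, normal_dp, normal_ad_ref,
                        baseq, sor, vaf, tpm) -> list[str]:
    failed = []
    if tumor_dp < _DEFAULTS["tumor_dp_min"]:
        failed.append("TUMOR_DP")
    if normal_dp < _DEFAULTS["normal_dp_min"]:
        failed.append("NORMAL_DP")
    if tumor_ad < _DEFAULTS["tumor_ad_min"]:
        failed.append("TUMOR_AD")
    if normal_ad_ref < _DEFAULTS["normal_ad_min"]:
        failed.append("NORMAL_AD")
    if baseq < _DEFAULTS["base_quality_min"]:
        failed.append("BASEQ")
    if sor > _DEFAULTS["sor_max"]:
        failed.append("SOR")
    if vaf < _DEFAULTS["vaf_min"]:
        failed.append("VAF")
    if tpm < _DEFAULTS["tpm_min"]:
        failed.append("TPM")
    return failed


def generate_cohort(config: CohortConfig, out_dir: str | Path,
                    planted_failures: Mapping[str, int] | None = None,
                    ) -> CohortBundle:
    """Emit a reproducible synthetic cohort bundle into ``out_dir``.

    When ``planted_failures`` maps rule names (e.g. ``{"VAF": 30}``) to
    counts, that many variants are forced to violate exactly that one rule
    while every remaining variant is coerced into safely passing ranges, so
    the truth table's pass/fail partition is exact by construction.  Without
    it, all metrics are free draws from the configured distributions and the
    truth verdicts come from a straight-line evaluation of the default
    thresholds.
    """
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    coerce = planted_failures is not None

    # ---- genes ----------------------------------------------------------
    genes = []
    for i in range(config.n_genes):
        n_aa = int(rng.integers(config.protein_len_min,
                                config.protein_len_max + 1))
        tpm = float(rng.lognormal(config.tpm_log_mean, config.tpm_log_sigma))
        if coerce:
            tpm = max(tpm, 1.5)  # background genes must pass the TPM rule
        genes.append(dict(
            gene_id=f"g{i:03d}", symbol=f"GENE{i:03d}", contig=f"ctg{i:03d}",
            cds=_random_cds(rng, n_aa), n_aa=n_aa,
            strand="-" if rng.random() < config.reverse_strand_fraction else "+",
            multi=rng.random() < config.multi_exon_fraction,
            tpm=round(tpm, 4)))

    # ---- genome + transcript models -------------------------------------
    fasta_path, gff_path = out / "genome.fa", out / "models.gff3"
    flank = config.flank
    with fasta_path.open("w") as fa, gff_path.open("w") as gff:
        gff.write("##gff-version 3\n")
        for g in genes:
            cds_genomic = g["cds"]
            if g["strand"] == "-":
                cds_genomic = str(Seq(cds_genomic).reverse_complement())
            if g["multi"]:
                cut = (len(cds_genomic) // 2) // 3 * 3  # codon-aligned split
                intron = "".join(_BASES[int(b)] for b in rng.integers(0, 4, 30))
                seq_core = cds_genomic[:cut] + intron + cds_genomic[cut:]
                intervals = [(flank + 1, flank + cut),
                             (flank + cut + 31, flank + len(cds_genomic) + 30)]
            else:
                seq_core = cds_genomic
                intervals = [(flank + 1, flank + len(cds_genomic))]
            lflank = "".join(_BASES[int(b)] for b in rng.integers(0, 4, flank))
            rflank = "".join(_BASES[int(b)] for b in rng.integers(0, 4, flank))
            contig_seq = lflank + seq_core + rflank
            fa.write(f">{g['contig']}\n")
            for k in range(0, len(contig_seq), 70):
                fa.write(contig_seq[k:k + 70] + "\n")
            g["intervals"] = intervals
            g["contig_len"] = len(contig_seq)
            ordered = intervals if g["strand"] == "+" else intervals[::-1]
            phases, acc = {}, 0
            for s, e in ordered:
                phases[(s, e)] = (3 - acc % 3) % 3
                acc += e - s + 1
            tid = f"tx_{g['gene_id']}"
            for s, e in intervals:
                gff.write(f"{g['contig']}\trnaneo\tCDS\t{s}\t{e}\t.\t"
                          f"{g['strand']}\t{phases[(s, e)]}\t"
                          f"ID=cds_{tid}_{s};Parent={tid};gene={g['symbol']}\n")

    # ---- variants --------------------------------------------------------
    plant: list[str | None] = []
    if coerce:
        unknown = set(planted_failures) - set(PLANTABLE_RULES)
        if unknown:
            raise ValidationError(f"cannot plant failures for rules {unknown}")
        for rule, count in sorted(planted_failures.items()):
            plant += [rule] * count
        if len(plant) > config.n_variants:
            raise ValidationError("more planted failures than variants")
    plant += [None] * (config.n_variants - len(plant))
    plant = [plant[i] for i in rng.permutation(config.n_variants)]
    # TPM plants need a gene with no other variant on it: place them while
    # unused genes remain (stable sort keeps the rest shuffled).
    plant.sort(key=lambda r: r != "TPM")

    def genomic_pos(g, cds_offset: int) -> int:
        """Map a 0-based CDS offset to a 1-based genomic position."""
        target = (cds_offset if g["strand"] == "+"
                  else len(g["cds"]) - 1 - cds_offset)
        acc = 0
        for s, e in g["intervals"]:
            size = e - s + 1
            if target < acc + size:
                return s + (target - acc)
            acc += size
        raise AssertionError("offset outside CDS")

    rows, truth_rows = [], []
    used_positions: set[tuple[str, int]] = set()
    blocked_genes: set[str] = set()  # genes dedicated to a TPM plant
    vi, attempts = 0, 0
    while vi < config.n_variants:
        attempts += 1
        if attempts > config.n_variants * 200:
            raise ValidationError(
                "could not place the requested variants in the CDS space")
        rule = plant[vi]
        g = genes[int(rng.integers(0, len(genes)))]
        if g["gene_id"] in blocked_genes:
            continue
        if rule == "TPM" and any(t["gene_id"] == g["gene_id"]
                                 for t in truth_rows):
            continue  # TPM plants need a dedicated gene

        u = rng.random()
        if u < config.fraction_missense:
            kind = "missense"
        elif u < config.fraction_missense + config.fraction_synonymous:
            kind = "synonymous"
        else:
            kind = "frameshift"
        if kind == "frameshift" and (g["strand"] == "-" or g["multi"]):
            continue  # indels planted on simple plus-strand genes only

        aa_pos = int(rng.integers(2, g["n_aa"]))
        if kind == "frameshift":
            cds_offset = (aa_pos - 1) * 3
            anchor = g["cds"][cds_offset - 1]
            ref_vcf = anchor + g["cds"][cds_offset]
            alt_vcf = anchor
            pos_vcf = genomic_pos(g, cds_offset - 1)
            if genomic_pos(g, cds_offset) != pos_vcf + 1:
                continue  # deletion straddles an intron boundary
        else:
            pick = _pick_substitution(rng, g["cds"], aa_pos,
                                      want_missense=(kind == "missense"))
            if pick is None:
                continue
            cds_offset, ref_base, alt_base = pick
            pos_vcf = genomic_pos(g, cds_offset)
            if g["strand"] == "-":
                ref_vcf = str(Seq(ref_base).complement())
                alt_vcf = str(Seq(alt_base).complement())
            else:
                ref_vcf, alt_vcf = ref_base, alt_base

        if any((g["contig"], p) in used_positions
               for p in (pos_vcf - 1, pos_vcf, pos_vcf + 1)):
            continue

        # ---- per-variant sequencing metrics -----------------------------
        tumor_dp = _nb_draw(rng, config.dp_mean, config.dp_dispersion)
        vaf = float(rng.beta(config.vaf_alpha, config.vaf_beta))
        normal_dp = _nb_draw(rng, config.normal_dp_mean, config.dp_dispersion)
        baseq = float(np.round(rng.normal(32.0, 5.0), 1))
        sor = float(np.round(abs(rng.normal(1.5, 1.0)), 3))
        tpm = g["tpm"]

        if coerce:
            # Background passes every rule with margin ...
            tumor_dp = max(tumor_dp, 60)
            normal_dp = max(normal_dp, 35)
            vaf = min(max(vaf, 0.10), 0.95)
            baseq = max(baseq, 25.0)
            sor = min(sor, 4.0)
            tumor_ad = max(int(round(vaf * tumor_dp)), 6)
            # ... and the planted rule is violated in isolation.
            if rule == "TUMOR_DP":
                tumor_dp = int(rng.integers(10, 50))
                tumor_ad = max(int(round(vaf * tumor_dp)), 6)
            elif rule == "NORMAL_DP":
                normal_dp = int(rng.integers(5, 30))
            elif rule == "TUMOR_AD":
                tumor_ad = int(rng.integers(3, 5))     # < 5
                tumor_dp = tumor_ad * 20               # VAF exactly 0.05 (passes)
            elif rule == "BASEQ":
                baseq = float(np.round(rng.uniform(5.0, 19.5), 1))
            elif rule == "SOR":
                sor = float(np.round(rng.uniform(5.1, 9.0), 3))
            elif rule == "VAF":
                target = float(rng.uniform(0.01, 0.044))
                tumor_ad = int(rng.integers(5, 9))     # keep AD passing
                tumor_dp = int(np.ceil(tumor_ad / target)) + 1
            elif rule == "TPM":
                tpm = float(np.round(rng.uniform(0.0, 0.95), 4))
        else:
            tumor_ad = min(max(int(round(vaf * tumor_dp)), 0), tumor_dp)

        tumor_ad = min(tumor_ad, tumor_dp)
        vaf_actual = tumor_ad / tumor_dp if tumor_dp > 0 else 0.0
        normal_ad_ref = max(normal_dp - int(rng.integers(0, 3)), 0)
        if coerce and rule == "NORMAL_AD":
            normal_ad_ref = int(rng.integers(0, 3))    # < 3

        expected_failed = _truth_failed_rules(
            tumor_dp, tumor_ad, normal_dp, normal_ad_ref, baseq, sor,
            vaf_actual, tpm)
        if coerce and expected_failed != ([rule] if rule else []):
            continue  # the planted violation bled into another rule; redraw

        used_positions.add((g["contig"], pos_vcf))
        if coerce and rule == "TPM":
            g["tpm"] = round(tpm, 4)
            blocked_genes.add(g["gene_id"])

        rows.append(dict(
            contig=g["contig"], pos=pos_vcf, ref=ref_vcf, alt=alt_vcf,
            tumor_dp=tumor_dp, tumor_ad=tumor_ad, normal_dp=normal_dp,
            normal_ad_ref=normal_ad_ref, baseq=baseq, sor=sor))

        if kind == "frameshift":
            ref_aa = str(Seq(g["cds"][(aa_pos - 1) * 3:aa_pos * 3]).translate())
            aa_change = f"{ref_aa}/fs"
        else:
            codon = g["cds"][(aa_pos - 1) * 3: aa_pos * 3]
            within = cds_offset - (aa_pos - 1) * 3
            alt_codon = codon[:within] + alt_base + codon[within + 1:]
            aa_change = (f"{Seq(codon).translate()}/"
                         f"{Seq(alt_codon).translate()}")
        truth_rows.append(dict(
            variant_key=f"{g['contig']}:{pos_vcf}:{ref_vcf}:{alt_vcf}",
            gene_id=g["gene_id"], gene_symbol=g["symbol"],
            consequence=kind, aa_pos=aa_pos, aa_change=aa_change,
            tpm=round(tpm, 4), vaf=round(vaf_actual, 6),
            planted_rule=rule if rule else "",
            expected_failed_rules=",".join(expected_failed),
            expected_pass=not expected_failed))
        vi += 1

    # ---- expression ------------------------------------------------------
    expr_path = out / "expression.tsv"
    with expr_path.open("w") as fh:
        fh.write("gene_id\tgene_symbol\tTPM\n")
        for g in genes:
            fh.write(f"{g['gene_id']}\t{g['symbol']}\t{g['tpm']:.4f}\n")

    # ---- VCF -------------------------------------------------------------
    vcf_path = out / "somatic.vcf"
    rows.sort(key=lambda r: (r["contig"], r["pos"]))
    with vcf_path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rnaneo-fixtures\n")
        for g in genes:
            fh.write(f"##contig=<ID={g['contig']},length={g['contig_len']}>\n")
        fh.write('##INFO=<ID=SOR,Number=1,Type=Float,'
                 'Description="Strand odds ratio">\n')
        fh.write('##INFO=<ID=MBQ,Number=1,Type=Float,'
                 'Description="Median base quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t"
                 "FORMAT\tTUMOR\tNORMAL\n")
        for r in rows:
            t_ref = r["tumor_dp"] - r["tumor_ad"]
            n_alt = r["normal_dp"] - r["normal_ad_ref"]
            fh.write(
                f"{r['contig']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t.\t"
                f"PASS\tSOR={r['sor']:.3f};MBQ={r['baseq']:.1f}\tGT:DP:AD\t"
                f"0/1:{r['tumor_dp']}:{t_ref},{r['tumor_ad']}\t"
                f"0/0:{r['normal_dp']}:{r['normal_ad_ref']},{n_alt}\n")

    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return CohortBundle(directory=out, fasta=fasta_path, gff3=gff_path,
                        vcf=vcf_path, expression=expr_path, truth=truth)


# ---------------------------------------------------------------------------
# Packaged candidate tables
# ---------------------------------------------------------------------------

def _table_path(table_id: int):
    return resources.files("rnaneo.data.paper_tables") / f"table{table_id}.tsv"


def load_paper_tables(table_id: int,
                      verify_checksum: bool = True) -> list[NeoantigenRecord]:
    """Load one of the five packaged published candidate tables (1–5).

    Tables 1/3/5 hold RNA-derived candidates (two mouse cell lines and one
    breast-cancer patient); 2/4 hold the matched conventional (WES-based)
    candidates.  Synthesis-failure flags and cross-references to the paired
    table are preserved.
    """
    if table_id not in (1, 2, 3, 4, 5):
        raise ValueError(f"unknown table id {table_id}; expected 1..5")
    raw = _table_path(table_id).read_bytes()
    if verify_checksum:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != PAPER_TABLE_CHECKSUMS[table_id]:
            raise ValidationError(
                f"packaged table {table_id} checksum mismatch ({digest}); "
                "the transcription was modified")
    df = pd.read_csv(io.BytesIO(raw), sep="\t")
    records = []
    for _, row in df.iterrows():
        pep = str(row["augmented_peptide"])
        cross = row.get("cross_ref")
        records.append(NeoantigenRecord(
            neoantigen_id=str(row["neoantigen_id"]),
            allele=parse_allele(str(row["hla_allele"])),
            allele_frequency=float(row["allele_frequency"]),
            aa_change=str(row["amino_acid_change"]),
            gene_symbol=str(row["gene_symbol"]),
            peptide_position=int(row["peptide_position"]),
            mut_ic50=float(row["mut_mhc_ic50"]),
            priority_score=float(row["priority_score"]),
            augmented_peptide=pep,
            synthesis_failed=bool(row["synthesis_failed"]),
            truncated=len(pep) not in (27, 31),
            cross_ref=str(cross) if pd.notna(cross) else None,
        ))
    return records
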