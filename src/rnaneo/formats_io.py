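"""Input/output layer and canonical in-memory records.

Everything external the pipeline touches — VCF v4.2 somatic calls, gene-level
expression tables, MHC/HLA allele names (human ``HLA-A02:07`` or seq2HLA-style
genotype files, mouse ``H-2-Kd``), transcript models (FASTA + GFF3 CDS
features) and the final candidate table — is parsed here into plain
dataclasses.  Coordinate conventions are converted at this boundary only:
genomic positions are 1-based inclusive externally (VCF/GFF3) and 0-based
half-open internally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio.Seq import Seq

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

#: Candidate-table column order (mirrors the published per-candidate schema).
CANDIDATE_COLUMNS = [
    "neoantigen_id",
    "hla_allele",
    "allele_frequency",
    "amino_acid_change",
    "gene_symbol",
    "peptide_position",
    "mut_mhc_ic50",
    "priority_score",
    "augmented_peptide",
    "synthesis_failed",
]


class ConfigurationError(ValueError):
    """A run was configured inconsistently (bad sample name, predictor, ...)."""


class RecordParseError(ValueError):
    """A single input record could not be parsed; the message names the site."""


class ValidationError(ValueError):
    """An input value violates a documented domain constraint."""


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SomaticVariant:
    """One RNA-seq-derived somatic variant call (one ALT allele at one site).

    ``vaf`` is the tumor variant allele fraction ``tumor_ad_alt / tumor_dp``.
    Quality annotations that were absent from the VCF are stored as ``None``,
    never silently coerced to 0.
    """

    chrom: str
    pos: int  # 1-based genomic position, as in the VCF
    ref_allele: str
    alt_allele: str
    variant_class: str  # SNV | insertion | deletion
    tumor_dp: int
    tumor_ad_alt: int
    normal_dp: int | None = None
    normal_ad_ref: int | None = None
    normal_ad_alt: int | None = None
    base_quality: float | None = None
    base_quality_source: str | None = None  # INFO key used, or "QUAL" fallback
    sor: float | None = None
    vaf: float | None = None

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValidationError(
                f"{self.key()}: REF and ALT alleles are identical")
        if self.tumor_ad_alt > self.tumor_dp:
            raise ValidationError(
                f"{self.key()}: tumor AD {self.tumor_ad_alt} exceeds DP {self.tumor_dp}")
        if (self.normal_dp is not None and self.normal_ad_ref is not None
                and self.normal_ad_ref > self.normal_dp):
            raise ValidationError(
                f"{self.key()}: normal ref AD exceeds normal DP")
        if self.vaf is not None:
            if not 0.0 <= self.vaf <= 1.0:
                raise ValidationError(f"{self.key()}: VAF {self.vaf} outside [0, 1]")
            if self.tumor_dp > 0 and abs(
                    self.vaf - self.tumor_ad_alt / self.tumor_dp) > 1e-6:
                raise ValidationError(
                    f"{self.key()}: VAF {self.vaf} inconsistent with "
                    f"AD/DP {self.tumor_ad_alt}/{self.tumor_dp}")

    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref_allele}:{self.alt_allele}"


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    gene_symbol: str
    tpm: float
    rpkm: float | None = None

    def __post_init__(self):
        if self.tpm < 0:
            raise ValidationError(f"gene {self.gene_id}: negative TPM {self.tpm}")


# Class-II locus prefixes for both species; everything else with a known
# prefix is class I.
_CLASS_II_LOCI = {"DRA", "DRB1", "DRB3", "DRB4", "DRB5",
                  "DQA1", "DQB1", "DPA1", "DPB1", "H2-IA", "H2-IE"}
_HUMAN_CLASS_I_LOCI = {"A", "B", "C", "E", "F", "G"}


@dataclass(frozen=True)
class MhcAllele:
    """A typed MHC allele, human (HLA) or mouse (H-2), class I or II.

    ``raw_name`` round-trips: :meth:`serialize` returns it unchanged, so any
    dialect we accept (``HLA-A02:07``, ``H-2-Kd``, ``H2-Ld``, ``DRB1_1501``,
    paired ``HLA-DPA10202-DPB10202``) survives a parse/serialize cycle.
    """

    raw_name: str
    mhc_class: str          # "I" | "II"
    species: str            # "human" | "mouse"
    locus: str              # e.g. "A", "DRB1", "H2-K"; alpha locus if paired
    paired: bool = False
    beta_locus: str | None = None

    def serialize(self) -> str:
        return self.raw_name

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.raw_name


_MOUSE_RE = re.compile(r"^H-?2-?(IA|IE|[KDLQ])([a-z])$")
_HUMAN_CLASSII_PAIR_RE = re.compile(
    r"^(?:HLA-)?(D[PQ]A1)\*?(\d+)-(?:HLA-)?(D[PQ]B1)\*?(\d+)$")
_HUMAN_UNDERSCORE_RE = re.compile(r"^(D[RQP][AB]?\d?)_(\d{4})$")
_HUMAN_CLASSI_RE = re.compile(r"^HLA-([A-G])\*?(\d{2}):?(\d{2,3})$")
_HUMAN_CLASSII_SINGLE_RE = re.compile(r"^HLA-(D[RQP][AB]\d?)\*?(\d+)(?::(\d+))?$")


def parse_allele(name: str) -> MhcAllele:
    """Parse an MHC allele name into species/class/locus.

    Accepts the human 4-digit ``HLA-A02:07`` style, underscore genotype names
    like ``DRB1_1501``, paired class-II alpha/beta names like
    ``HLA-DPA10202-DPB10202``, and mouse haplotype names ``H-2-Kd`` /
    ``H2-Ld`` / ``H-2-IAb``.
    """
    token = name.strip()
    if not token:
        raise RecordParseError("empty allele name")

    m = _MOUSE_RE.match(token)
    if m:
        locus = f"H2-{m.group(1)}"
        cls = "II" if m.group(1) in ("IA", "IE") else "I"
        return MhcAllele(raw_name=token, mhc_class=cls, species="mouse",
                         locus=locus)

    m = _HUMAN_CLASSII_PAIR_RE.match(token)
    if m:
        return MhcAllele(raw_name=token, mhc_class="II", species="human",
                         locus=m.group(1), paired=True, beta_locus=m.group(3))

    m = _HUMAN_UNDERSCORE_RE.match(token)
    if m:
        return MhcAllele(raw_name=token, mhc_class="II", species="human",
                         locus=m.group(1))

    m = _HUMAN_CLASSI_RE.match(token)
    if m:
        return MhcAllele(raw_name=token, mhc_class="I", species="human",
                         locus=m.group(1))

    m = _HUMAN_CLASSII_SINGLE_RE.match(token)
    if m:
        return MhcAllele(raw_name=token, mhc_class="II", species="human",
                         locus=m.group(1))

    raise RecordParseError(f"unrecognized MHC allele name: {token!r}")


def read_allele_list(path: str | Path) -> list[MhcAllele]:
    """Read alleles from a plain list or a seq2HLA-style two-column genotype.

    A line ``A\t02:07`` (locus, 4-digit allele) is joined to ``HLA-A02:07``;
    a line that already parses on its own is taken verbatim.  ``'`` markers
    (seq2HLA low-confidence) and ``hoz``/``no`` calls are stripped/skipped.
    """
    alleles: list[MhcAllele] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) >= 2:
            locus, call = fields[0].strip(), fields[1].strip().rstrip("'")
            if call.lower() in ("no", "hoz", "-"):
                continue
            if locus.upper() in _HUMAN_CLASS_I_LOCI or locus.upper().startswith("D"):
                prefix = "HLA-" if not locus.upper().startswith("D") else ""
                name = f"{prefix}{locus}{call}" if prefix else f"{locus}_{call.replace(':', '')}"
                alleles.append(parse_allele(name))
                continue
        alleles.append(parse_allele(line.split("\t")[0]))
    return alleles


@dataclass(frozen=True)
class TranscriptModel:
    """A protein-coding transcript: ordered CDS intervals plus its protein.

    ``cds_intervals`` are 1-based inclusive genomic coordinates in genomic
    order; for minus-strand transcripts the spliced CDS is the reverse
    complement of their concatenation.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    cds_seq: str
    protein_seq: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValidationError(f"{self.transcript_id}: bad strand {self.strand!r}")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    def validate(self) -> None:
        """Check translation of the spliced CDS reproduces ``protein_seq``."""
        if self.cds_length % 3 != 0:
            raise ValidationError(
                f"{self.transcript_id}: CDS length {self.cds_length} not a multiple of 3")
        translated = translate_cds(self.cds_seq)
        if translated != self.protein_seq:
            raise ValidationError(
                f"{self.transcript_id}: CDS translation does not match protein_seq")

    def genomic_to_cds(self, pos: int) -> int | None:
        """Map a 1-based genomic position to a 0-based CDS offset, or None."""
        offset = 0
        for start, end in self.cds_intervals:
            if start <= pos <= end:
                within = pos - start
                if self.strand == "+":
                    return offset + within
                return self.cds_length - 1 - (offset + within)
            offset += end - start + 1
        return None


def translate_cds(cds_seq: str, to_first_stop: bool = False) -> str:
    """Translate a CDS with the standard nuclear code; trailing stop dropped."""
    usable = cds_seq[: len(cds_seq) - len(cds_seq) % 3]
    aa = str(Seq(usable).translate())
    if to_first_stop or aa.endswith("*"):
        stop = aa.find("*")
        if stop >= 0:
            return aa[:stop]
    return aa


@dataclass(frozen=True)
class NeoantigenRecord:
    """The joined, scored unit — one row of the final candidate table."""

    neoantigen_id: str
    allele: MhcAllele
    allele_frequency: float
    aa_change: str                 # "REF/ALT" single-letter pair
    gene_symbol: str
    peptide_position: int          # 1-based mutated-residue index in the epitope
    mut_ic50: float
    priority_score: float
    augmented_peptide: str
    wt_ic50: float | None = None
    tpm: float | None = None
    synthesis_failed: bool = False
    truncated: bool = False        # augmented peptide shorter than the window
    cross_ref: str | None = None   # matching id in the other method's table

    def __post_init__(self):
        if not self.truncated and len(self.augmented_peptide) not in (27, 31):
            raise ValidationError(
                f"{self.neoantigen_id}: augmented peptide length "
                f"{len(self.augmented_peptide)} is neither 27 nor 31 and not "
                "flagged truncated")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, tumor_sample: str,
             normal_sample: str | None = None) -> list[SomaticVariant]:
    """Read a VCF v4.2 of somatic calls into one record per ALT allele.

    FORMAT ``DP``/``AD`` must be present for the tumor sample; the VAF is
    computed from them.  Site-level ``SOR`` and base quality (INFO ``MBQ`` or
    ``QA``, falling back to the record QUAL) are carried along when present
    and stored as ``None`` otherwise.
    """
    variants: list[SomaticVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if tumor_sample not in samples:
            raise ConfigurationError(
                f"tumor sample {tumor_sample!r} not in VCF samples {samples}")
        if normal_sample is not None and normal_sample not in samples:
            raise ConfigurationError(
                f"normal sample {normal_sample!r} not in VCF samples {samples}")
        for rec in vcf:
            tumor = rec.samples[tumor_sample]
            dp = tumor.get("DP")
            ad = tumor.get("AD")
            site = f"{rec.chrom}:{rec.pos}"
            if dp is None or ad is None or all(a is None for a in ad):
                raise RecordParseError(
                    f"site {site}: tumor DP/AD missing from FORMAT")
            sor = rec.info.get("SOR")
            if isinstance(sor, tuple):
                sor = sor[0]
            baseq, baseq_src = None, None
            for key in ("MBQ", "QA"):
                if key in rec.info:
                    val = rec.info[key]
                    baseq = float(val[0] if isinstance(val, tuple) else val)
                    baseq_src = key
                    break
            if baseq is None and rec.qual is not None:
                baseq, baseq_src = float(rec.qual), "QUAL"

            normal_dp = normal_ad_ref = normal_ad_alt = None
            if normal_sample is not None:
                normal = rec.samples[normal_sample]
                normal_dp = normal.get("DP")
                nad = normal.get("AD")
                if nad is not None and nad[0] is not None:
                    normal_ad_ref = int(nad[0])

            for alt_idx, alt in enumerate(rec.alts or (), start=1):
                ad_alt = int(ad[alt_idx]) if len(ad) > alt_idx and ad[alt_idx] is not None else 0
                vaf = ad_alt / dp if dp and dp > 0 else None
                normal_ad_alt = None
                if normal_sample is not None:
                    normal = rec.samples[normal_sample]
                    nad = normal.get("AD")
                    if nad is not None and len(nad) > alt_idx and nad[alt_idx] is not None:
                        normal_ad_alt = int(nad[alt_idx])
                variants.append(SomaticVariant(
                    chrom=rec.chrom, pos=rec.pos,
                    ref_allele=rec.ref.upper(), alt_allele=str(alt).upper(),
                    variant_class=classify_variant(rec.ref, str(alt)),
                    tumor_dp=int(dp), tumor_ad_alt=ad_alt,
                    normal_dp=int(normal_dp) if normal_dp is not None else None,
                    normal_ad_ref=normal_ad_ref, normal_ad_alt=normal_ad_alt,
                    base_quality=baseq, base_quality_source=baseq_src,
                    sor=float(sor) if sor is not None else None, vaf=vaf))
    return variants


def classify_variant(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "insertion"
    if len(alt) < len(ref):
        return "deletion"
    return "SNV"  # MNV treated as substitution


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene-level expression TSV into a DataFrame indexed by gene_id.

    Requires ``gene_id`` and ``TPM`` (case-insensitive) columns; an optional
    ``gene_symbol`` column defaults to the gene_id and ``RPKM`` is carried if
    present.  Duplicate gene ids and negative TPMs are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "gene_id" not in cols or "tpm" not in cols:
        raise RecordParseError(
            f"expression table {path}: needs gene_id and TPM columns, "
            f"found {list(df.columns)}")
    out = pd.DataFrame({
        "gene_id": df[cols["gene_id"]].astype(str),
        "gene_symbol": df[cols["gene_symbol"]].astype(str)
        if "gene_symbol" in cols else df[cols["gene_id"]].astype(str),
        "tpm": pd.to_numeric(df[cols["tpm"]]),
    })
    if "rpkm" in cols:
        out["rpkm"] = pd.to_numeric(df[cols["rpkm"]])
    dupes = out["gene_id"][out["gene_id"].duplicated()]
    if len(dupes):
        raise ValidationError(
            f"duplicate gene_id in expression table: {sorted(set(dupes))}")
    if (out["tpm"] < 0).any():
        bad = out.loc[out["tpm"] < 0, "gene_id"].tolist()
        raise ValidationError(f"negative TPM for genes: {bad}")
    return out.set_index("gene_id", drop=False)


def read_transcript_models(fasta_path: str | Path,
                           gff3_path: str | Path) -> list[TranscriptModel]:
    """Build transcript models from a genome FASTA and a GFF3 of CDS features.

    CDS features are grouped by their ``Parent`` (or ``transcript_id``)
    attribute; ``gene`` (or ``gene_id``) gives the gene symbol.  Each model is
    validated: spliced CDS length divisible by 3 and translating cleanly.
    """
    import gffutils
    import pyfaidx

    genome = pyfaidx.Fasta(str(fasta_path))
    db = gffutils.create_db(str(gff3_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    grouped: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for cds in db.features_of_type("CDS"):
        parent = (cds.attributes.get("Parent")
                  or cds.attributes.get("transcript_id") or [cds.id])[0]
        gene = (cds.attributes.get("gene")
                or cds.attributes.get("gene_id") or [parent])[0]
        grouped.setdefault(parent, []).append(cds)
        meta[parent] = (gene, cds.seqid, cds.strand)

    models = []
    for tid, features in grouped.items():
        gene, chrom, strand = meta[tid]
        features.sort(key=lambda f: f.start)
        intervals = tuple((f.start, f.end) for f in features)
        spliced = "".join(str(genome[chrom][s - 1:e]) for s, e in intervals).upper()
        if strand == "-":
            spliced = str(Seq(spliced).reverse_complement())
        model = TranscriptModel(
            transcript_id=tid, gene_symbol=gene, chrom=chrom, strand=strand,
            cds_intervals=intervals, cds_seq=spliced,
            protein_seq=translate_cds(spliced))
        model.validate()
        models.append(model)
    models.sort(key=lambda m: m.transcript_id)
    return models


# ---------------------------------------------------------------------------
# Candidate-table writer / reader
# ---------------------------------------------------------------------------

def candidates_to_frame(records: Sequence[NeoantigenRecord]) -> pd.DataFrame:
    rows = [{
        "neoantigen_id": r.neoantigen_id,
        "hla_allele": r.allele.serialize(),
        "allele_frequency": r.allele_frequency,
        "amino_acid_change": r.aa_change,
        "gene_symbol": r.gene_symbol,
        "peptide_position": r.peptide_position,
        "mut_mhc_ic50": r.mut_ic50,
        "priority_score": r.priority_score,
        "augmented_peptide": r.augmented_peptide,
        "synthesis_failed": r.synthesis_failed,
    } for r in records]
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def write_candidates(records: Sequence[NeoantigenRecord],
                     path: str | Path) -> None:
    """Serialize scored candidates as TSV in the canonical column order."""
    candidates_to_frame(records).to_csv(path, sep="\t", index=False)


def read_candidates(path: str | Path) -> list[NeoantigenRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        pep = str(row["augmented_peptide"])
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
            synthesis_failed=_as_bool(row["synthesis_failed"]),
            truncated=len(pep) not in (27, 31),
            cross_ref=(str(row["cross_ref"])
                       if "cross_ref" in df.columns and pd.notna(row.get("cross_ref"))
                       else None),
        ))
    return records


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("true", "1", "yes")
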