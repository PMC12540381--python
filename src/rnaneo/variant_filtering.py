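"""Somatic-variant filtering cascade for RNA-seq calls.

Eight rules are evaluated for every variant — tumor depth, normal depth,
tumor alt-allele depth, normal allele depth, base quality, strand-odds-ratio,
variant allele fraction and gene expression — with the defaults used for
RNA-only somatic screening: DP ≥ 50× (tumor) / ≥ 30× (normal), AD ≥ 5×
(tumor) / ≥ 3× (normal), base quality ≥ Q20, SOR ≤ 5.0, VAF ≥ 5 % and
TPM ≥ 1.  All comparisons are inclusive on the stated side.  Rules are never
short-circuited, so each verdict carries the complete list of failed rules
and funnel-style summaries stay consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import ConfigurationError, SomaticVariant, ValidationError

#: Rule identifiers in evaluation (and reporting) order.
RULE_ORDER = ["TUMOR_DP", "NORMAL_DP", "TUMOR_AD", "NORMAL_AD",
              "BASEQ", "SOR", "VAF", "TPM", "NO_EXPRESSION"]


@dataclass(frozen=True)
class FilterThresholds:
    """All cutoffs of the filtering cascade; minima are inclusive (≥), the
    strand-bias cutoff is an inclusive maximum (≤)."""

    tumor_dp_min: int = 50
    normal_dp_min: int = 30
    tumor_ad_min: int = 5
    normal_ad_min: int = 3
    base_quality_min: float = 20.0
    sor_max: float = 5.0
    vaf_min: float = 0.05
    tpm_min: float = 1.0
    #: "ref_support" requires normal reference-allele depth ≥ normal_ad_min
    #: (the normal genotype is evaluable); "alt_at_most" instead rejects
    #: variants whose normal ALT support exceeds normal_ad_min (germline
    #: contamination guard).
    normal_ad_interpretation: str = "ref_support"

    def __post_init__(self):
        for name in ("tumor_dp_min", "normal_dp_min", "tumor_ad_min",
                     "normal_ad_min", "base_quality_min", "sor_max", "tpm_min"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.vaf_min <= 1.0:
            raise ValidationError("vaf_min must lie in [0, 1]")
        if self.normal_ad_interpretation not in ("ref_support", "alt_at_most"):
            raise ConfigurationError(
                f"unknown normal_ad_interpretation "
                f"{self.normal_ad_interpretation!r}")


@dataclass(frozen=True)
class FilterVerdict:
    variant_key: str
    passed: bool
    failed_rules: tuple[str, ...]

    def __post_init__(self):
        if self.passed != (len(self.failed_rules) == 0):
            raise ValidationError(
                f"{self.variant_key}: passed flag inconsistent with failed_rules")


def compute_vaf(ad_alt: int, dp: int) -> float:
    """Variant allele fraction ``ad_alt / dp`` for ``dp > 0``."""
    if dp <= 0:
        raise ValidationError(f"VAF undefined for DP={dp}")
    if not 0 <= ad_alt <= dp:
        raise ValidationError(f"AD={ad_alt} outside [0, DP={dp}]")
    return ad_alt / dp


def apply_filters(variants: Sequence[SomaticVariant],
                  expression: pd.DataFrame,
                  gene_of: Mapping[str, str] | Callable[[SomaticVariant], str | None],
                  thresholds: FilterThresholds = FilterThresholds(),
                  tumor_only: bool = False) -> list[FilterVerdict]:
    """Evaluate every rule for every variant and return complete verdicts.

    ``gene_of`` maps a variant (by its ``chrom:pos:ref:alt`` key, or via a
    callable) to the gene symbol used for the expression join; a variant that
    resolves to no gene, or to a gene absent from the expression table, fails
    ``NO_EXPRESSION``.  In ``tumor_only`` mode (cell lines without a matched
    normal) the NORMAL_DP and NORMAL_AD rules pass vacuously.  Quality
    annotations recorded as absent (``None``) also pass vacuously rather than
    being treated as zero.
    """
    if isinstance(gene_of, Mapping):
        lookup = lambda v: gene_of.get(v.key())  # noqa: E731
    else:
        lookup = gene_of
    tpm_by_symbol = dict(zip(expression["gene_symbol"], expression["tpm"]))

    verdicts: list[FilterVerdict] = []
    for v in variants:
        failed: list[str] = []
        if v.tumor_dp < thresholds.tumor_dp_min:
            failed.append("TUMOR_DP")
        if not tumor_only:
            if v.normal_dp is None or v.normal_dp < thresholds.normal_dp_min:
                failed.append("NORMAL_DP")
        if v.tumor_ad_alt < thresholds.tumor_ad_min:
            failed.append("TUMOR_AD")
        if not tumor_only:
            if thresholds.normal_ad_interpretation == "ref_support":
                if (v.normal_ad_ref is None
                        or v.normal_ad_ref < thresholds.normal_ad_min):
                    failed.append("NORMAL_AD")
            else:  # alt_at_most
                if (v.normal_ad_alt is not None
                        and v.normal_ad_alt > thresholds.normal_ad_min):
                    failed.append("NORMAL_AD")
        if (v.base_quality is not None
                and v.base_quality < thresholds.base_quality_min):
            failed.append("BASEQ")
        if v.sor is not None and v.sor > thresholds.sor_max:
            failed.append("SOR")
        vaf = v.vaf
        if vaf is None and v.tumor_dp > 0:
            vaf = compute_vaf(v.tumor_ad_alt, v.tumor_dp)
        if vaf is None or vaf < thresholds.vaf_min:
            failed.append("VAF")
        gene = lookup(v)
        tpm = tpm_by_symbol.get(gene) if gene is not None else None
        if tpm is None:
            failed.append("NO_EXPRESSION")
        elif tpm < thresholds.tpm_min:
            failed.append("TPM")
        verdicts.append(FilterVerdict(variant_key=v.key(),
                                      passed=not failed,
                                      failed_rules=tuple(failed)))
    return verdicts


def summarize_filtering(verdicts: Iterable[FilterVerdict]) -> dict[str, int]:
    """Funnel summary: per-rule failure counts plus pass/fail/total counts.

    A variant failing several rules contributes to each rule's count but only
    once to the pass/fail totals.
    """
    counts = {rule: 0 for rule in RULE_ORDER}
    n_pass = n_total = 0
    for verdict in verdicts:
        n_total += 1
        if verdict.passed:
            n_pass += 1
        for rule in verdict.failed_rules:
            counts[rule] += 1
    counts["pass"] = n_pass
    counts["fail"] = n_total - n_pass
    counts["total"] = n_total
    return counts
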