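"""Candidate-set comparison: RNA-only versus conventional calls.

Two candidate lists are compared either at the variant level (canonical
``GENE:aa_pos:REF/ALT`` keys) or at the peptide level (augmented-peptide
strings), reporting set sizes, intersection, the matched keys, and the
Jaccard index.  A helper cross-labels the two top-N tables the way paired
published candidate lists annotate shared rows (e.g. ``C3(M6)``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .formats_io import ConfigurationError, NeoantigenRecord


@dataclass(frozen=True)
class OverlapReport:
    n_a: int
    n_b: int
    n_overlap: int
    overlap_keys: tuple[str, ...]
    jaccard: float

    def __post_init__(self):
        if self.n_overlap > min(self.n_a, self.n_b):
            raise ValueError("overlap larger than the smaller set")


def _record_key(record: NeoantigenRecord, level: str) -> str:
    if level == "variant":
        return (f"{record.gene_symbol.upper()}"
                f":{record.aa_change.upper()}")
    if level == "peptide":
        return record.augmented_peptide.upper()
    raise ConfigurationError(f"unknown comparison level {level!r}")


def overlap(set_a: Sequence[NeoantigenRecord | str],
            set_b: Sequence[NeoantigenRecord | str],
            level: str = "variant") -> OverlapReport:
    """Exact-key intersection of two candidate sets.

    Accepts either precomputed key strings or records (keyed by gene + amino
    acid change at the variant level, by augmented peptide at the peptide
    level).  Duplicate keys within a set are deduplicated before counting, so
    the report is symmetric and idempotent.
    """
    def keys(items) -> set[str]:
        out = set()
        for item in items:
            if isinstance(item, str):
                out.add(item.upper())
            else:
                out.add(_record_key(item, level))
        return out

    ka, kb = keys(set_a), keys(set_b)
    inter = sorted(ka & kb)
    denom = len(ka | kb)
    return OverlapReport(n_a=len(ka), n_b=len(kb), n_overlap=len(inter),
                         overlap_keys=tuple(inter),
                         jaccard=len(inter) / denom if denom else 0.0)


def annotate_overlap_ids(top_a: Sequence[NeoantigenRecord],
                         top_b: Sequence[NeoantigenRecord],
                         level: str = "variant",
                         ) -> tuple[list[NeoantigenRecord], list[NeoantigenRecord]]:
    """Cross-label shared candidates between two top-N lists.

    A record whose key appears in the other list gains that record's id as
    ``cross_ref`` (rendered ``C3(M6)``-style by the table writer); both lists
    are returned with labels applied.
    """
    from dataclasses import replace

    by_key_a = {_record_key(r, level): r for r in top_a}
    by_key_b = {_record_key(r, level): r for r in top_b}
    out_a = [replace(r, cross_ref=by_key_b[k].neoantigen_id)
             if (k := _record_key(r, level)) in by_key_b else r
             for r in top_a]
    out_b = [replace(r, cross_ref=by_key_a[k].neoantigen_id)
             if (k := _record_key(r, level)) in by_key_a else r
             for r in top_b]
    return out_a, out_b
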