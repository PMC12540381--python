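"""Weighted priority scoring, ranking and top-N candidate selection.

Each candidate is reduced to five bounded sub-scores — binding (log-scaled
mutant IC50, optionally sharpened by the mutant/wild-type differential),
expression (saturating TPM map), variant allele fraction, DNA–RNA mutation
concordance and antigen-presentation likelihood (from the predictor's
percentile rank) — combined as ``100 × Σ wᵢ sᵢ`` with weights normalised to
sum to one.  The published tables' printed priority scores come from an
unpublished weighting and are not a reproduction target; the defaults here
are equal weights, fully configurable.

Two cutoff policies coexist deliberately: *conventional* mode applies the
strict IC50 < 500 nM candidate gate before ranking; *RNA* mode ranks all
passing epitopes by priority score without a hard IC50 gate (the published
RNA-derived candidate lists contain entries far above 500 nM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .binding import DEFAULT_CANDIDATE_CUTOFF_NM, IC50_MAX_NM
from .formats_io import ConfigurationError, NeoantigenRecord, ValidationError


@dataclass(frozen=True)
class ScoringWeights:
    w_binding: float = 1.0
    w_expression: float = 1.0
    w_vaf: float = 1.0
    w_concordance: float = 1.0
    w_presentation: float = 1.0
    normalization: bool = True

    def __post_init__(self):
        vals = self.as_tuple()
        if any(w < 0 for w in vals):
            raise ValidationError("scoring weights must be >= 0")
        if not any(w > 0 for w in vals):
            raise ConfigurationError("at least one scoring weight must be > 0")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.w_binding, self.w_expression, self.w_vaf,
                self.w_concordance, self.w_presentation)

    def normalized(self) -> tuple[float, ...]:
        vals = self.as_tuple()
        if not self.normalization:
            return vals
        total = sum(vals)
        return tuple(w / total for w in vals)


@dataclass(frozen=True)
class SubScores:
    s_binding: float
    s_expression: float
    s_vaf: float
    s_concordance: float
    s_presentation: float

    def __post_init__(self):
        for name in ("s_binding", "s_expression", "s_vaf",
                     "s_concordance", "s_presentation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.s_binding, self.s_expression, self.s_vaf,
                self.s_concordance, self.s_presentation)


def _clamp(x: float, lo: float = 0.0, hi: float = 1.0) -> float:
    return max(lo, min(hi, x))


def subscores(mut_ic50: float,
              tpm: float,
              vaf: float,
              wt_ic50: float | None = None,
              concordant: bool | None = None,
              percent_rank: float | None = None,
              tpm_half_saturation: float = 10.0,
              wt_differential_baseline: float = 0.5) -> SubScores:
    """Map a joined candidate's raw metrics onto the five bounded sub-scores.

    * binding: ``clamp(1 − ln(IC50)/ln(50000))`` — 1 at 1 nM, 0 at 50 µM —
      multiplied, when the wild-type IC50 is known, by
      ``baseline + clamp(log10(wt/mut), 0, 1)`` so mutant-specific binders
      outrank shared ones; the product is re-clamped to [0, 1].
    * expression: ``log1p(TPM) / (log1p(TPM) + log1p(h))`` with
      half-saturation ``h`` (default 10 TPM).
    * vaf: the tumor allele fraction itself.
    * concordance: 1 when a matched DNA call supports the RNA variant; in
      RNA-only runs there is no DNA to check, so ``None`` scores 1.
    * presentation: ``1 − rank/100`` from the predictor's percentile rank,
      0.5 when no rank is available.
    """
    if mut_ic50 <= 0:
        raise ValidationError(f"mut_ic50 must be > 0, got {mut_ic50}")
    if not 0.0 <= vaf <= 1.0:
        raise ValidationError(f"vaf {vaf} outside [0, 1]")
    if tpm < 0:
        raise ValidationError(f"tpm {tpm} must be >= 0")

    s_binding = _clamp(1.0 - math.log(mut_ic50) / math.log(IC50_MAX_NM))
    if wt_ic50 is not None:
        diff = _clamp(math.log10(wt_ic50 / mut_ic50))
        s_binding = _clamp(s_binding * (wt_differential_baseline + diff))

    ltpm = math.log1p(tpm)
    s_expression = ltpm / (ltpm + math.log1p(tpm_half_saturation)) if ltpm > 0 else 0.0

    s_concordance = 1.0 if (concordant is None or concordant) else 0.0
    s_presentation = (0.5 if percent_rank is None
                      else _clamp(1.0 - percent_rank / 100.0))
    return SubScores(s_binding=s_binding, s_expression=s_expression,
                     s_vaf=vaf, s_concordance=s_concordance,
                     s_presentation=s_presentation)


def priority_score(sub: SubScores, weights: ScoringWeights = ScoringWeights(),
                   ) -> float:
    """``100 × Σ wᵢ sᵢ`` with normalised weights; lies in [0, 100]."""
    w = weights.normalized()
    return 100.0 * sum(wi * si for wi, si in zip(w, sub.as_tuple()))


def rank_and_select(records: Sequence[NeoantigenRecord],
                    n: int = 10) -> list[NeoantigenRecord]:
    """Top-``n`` records by descending priority score.

    Ties break by lower mutant IC50, then higher TPM, then gene symbol; the
    result is independent of the input permutation.
    """
    if n <= 0:
        raise ConfigurationError(f"top-N size must be positive, got {n}")
    ordered = sorted(records, key=lambda r: (
        -r.priority_score, r.mut_ic50,
        -(r.tpm if r.tpm is not None else 0.0),
        r.gene_symbol, r.neoantigen_id))
    return ordered[:n]


def mark_synthesis_failures(records: Sequence[NeoantigenRecord],
                            failed_ids: Iterable[str],
                            ) -> tuple[list[NeoantigenRecord], int]:
    """Flag peptides that failed chemical synthesis; return synthesized count.

    Flagged records stay in the list (the candidate table keeps them, marked)
    but are excluded from the synthesized count and from vaccine export.
    Unknown ids raise nothing — they are reported back via the return and a
    warning is the caller's choice.
    """
    failed = set(failed_ids)
    known = {r.neoantigen_id for r in records}
    annotated = [replace(r, synthesis_failed=(r.neoantigen_id in failed
                                              or r.synthesis_failed))
                 for r in records]
    n_synthesized = sum(1 for r in annotated if not r.synthesis_failed)
    unknown = failed - known
    if unknown:
        import warnings
        warnings.warn(f"synthesis-failure flags for unknown ids: {sorted(unknown)}",
                      stacklevel=2)
    return annotated, n_synthesized


def synthesized_count(records: Sequence[NeoantigenRecord]) -> int:
    """Number of candidates that were actually synthesized."""
    return sum(1 for r in records if not r.synthesis_failed)


def vaccine_export(records: Sequence[NeoantigenRecord]) -> list[NeoantigenRecord]:
    """Candidates eligible for vaccine formulation (synthesis succeeded)."""
    return [r for r in records if not r.synthesis_failed]
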