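"""Peptide–MHC binding prediction contract and built-in predictors.

External affinity engines (NetMHCpan / NetMHCIIpan) sit behind a small
adapter contract: a predictor takes peptides and an allele and returns one
:class:`BindingResult` per peptide, deterministically.  Three predictors
ship here:

* ``toy`` — a deterministic allele-seeded position-weight-matrix scorer for
  offline testing; not a trained model.
* ``table:<path>`` — replays a precomputed table (peptide, allele, IC50 nM,
  %rank), e.g. an exported NetMHCpan run.
* ``netmhcpan`` — a subprocess adapter that requires the external binary and
  fails loudly (never silently falling back) when it is absent.

The conventional candidate rule — keep peptides with predicted IC50 strictly
below 500 nM — lives here too.
"""

from __future__ import annotations

import hashlib
import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formats_io import (AA_ALPHABET, ConfigurationError, MhcAllele,
                         ValidationError)

IC50_MAX_NM = 50000.0
DEFAULT_CANDIDATE_CUTOFF_NM = 500.0
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class BindingResult:
    peptide: str
    allele: MhcAllele
    ic50: float                     # nM, in (0, 50000]
    percent_rank: float | None      # [0, 100]
    source: str

    def __post_init__(self):
        if not 0.0 < self.ic50 <= IC50_MAX_NM:
            raise ValidationError(
                f"IC50 {self.ic50} outside (0, {IC50_MAX_NM}] for {self.peptide}")
        if self.percent_rank is not None and not 0.0 <= self.percent_rank <= 100.0:
            raise ValidationError(
                f"percent rank {self.percent_rank} outside [0, 100]")


class PredictorUnavailableError(RuntimeError):
    """The requested external predictor cannot run in this environment."""


class BindingPredictor:
    """Adapter contract: deterministic per-(peptide, allele) affinity."""

    name = "abstract"

    def predict_one(self, peptide: str, allele: MhcAllele) -> BindingResult:
        raise NotImplementedError

    def predict(self, peptides: Sequence[str],
                allele: MhcAllele) -> list[BindingResult]:
        """One result per peptide, input order preserved, cached per run."""
        cache = getattr(self, "_cache", None)
        if cache is None:
            cache = self._cache = {}
        out = []
        for pep in peptides:
            key = (pep, allele.serialize())
            if key not in cache:
                cache[key] = self.predict_one(pep, allele)
            out.append(cache[key])
        return out


def _validate_peptide(peptide: str, min_len: int = 8, max_len: int = 15) -> None:
    if not min_len <= len(peptide) <= max_len:
        raise ValidationError(
            f"peptide length {len(peptide)} outside [{min_len}, {max_len}]: "
            f"{peptide!r}")
    bad = set(peptide) - AA_ALPHABET
    if bad:
        raise ValidationError(
            f"non-amino-acid characters {sorted(bad)} in peptide {peptide!r}")


class ToyPredictor(BindingPredictor):
    """Deterministic pseudo-affinity from an allele-seeded residue weight set.

    Each allele seeds (via SHA-256 of its canonical name) a weight per amino
    acid; a peptide's score sums its residue weights, counting the classical
    anchor positions — position 2 and the C-terminus — twice.  The score maps
    monotonically (logistic) onto (0, 50000] nM, so a higher score means a
    lower IC50, and a residue change at an anchor always moves the IC50
    further than the same change elsewhere.  No randomness at call time.
    """

    name = "toy"
    _SCALE = 2.0

    def __init__(self):
        self._matrices: dict[str, np.ndarray] = {}
        self._cache: dict = {}

    def _weights(self, allele: MhcAllele) -> np.ndarray:
        key = allele.serialize()
        if key not in self._matrices:
            digest = hashlib.sha256(f"toy-pwm-v1:{key}".encode()).digest()
            seed = int.from_bytes(digest[:4], "big")
            rng = np.random.default_rng(seed)
            self._matrices[key] = rng.normal(0.0, 1.0, size=len(AMINO_ACIDS))
        return self._matrices[key]

    def score(self, peptide: str, allele: MhcAllele) -> float:
        _validate_peptide(peptide)
        w = self._weights(allele)
        idx = [AMINO_ACIDS.index(aa) for aa in peptide]
        score = 0.0
        anchors = {1, len(peptide) - 1}  # 0-based: position 2 and C-terminus
        for i, j in enumerate(idx):
            score += w[j] * (2.0 if i in anchors else 1.0)
        return score

    def predict_one(self, peptide: str, allele: MhcAllele) -> BindingResult:
        score = self.score(peptide, allele)
        # Strictly decreasing logistic map onto (0, 50000); clamp away from 0.
        ic50 = IC50_MAX_NM / (1.0 + float(np.exp(score / self._SCALE)))
        ic50 = max(ic50, 1e-6)
        rank = 100.0 / (1.0 + float(np.exp(score / self._SCALE)))
        return BindingResult(peptide=peptide, allele=allele, ic50=ic50,
                             percent_rank=rank, source=self.name)


class TablePredictor(BindingPredictor):
    """Replay a precomputed binding table exactly.

    The table is a TSV with columns ``peptide``, ``allele``, ``ic50_nM`` and
    optional ``percent_rank``; a query for a (peptide, allele) pair absent
    from the table is an error, never an imputed value.
    """

    name = "table"

    def __init__(self, path: str | Path):
        df = pd.read_csv(path, sep="\t")
        required = {"peptide", "allele", "ic50_nM"}
        if not required.issubset(df.columns):
            raise ConfigurationError(
                f"binding table {path} needs columns {sorted(required)}, "
                f"found {list(df.columns)}")
        self._table: dict[tuple[str, str], tuple[float, float | None]] = {}
        for _, row in df.iterrows():
            rank = (float(row["percent_rank"])
                    if "percent_rank" in df.columns and pd.notna(row["percent_rank"])
                    else None)
            self._table[(str(row["peptide"]), str(row["allele"]))] = (
                float(row["ic50_nM"]), rank)
        self._cache: dict = {}

    def predict_one(self, peptide: str, allele: MhcAllele) -> BindingResult:
        key = (peptide, allele.serialize())
        if key not in self._table:
            raise KeyError(
                f"(peptide, allele) pair {key} not in precomputed table")
        ic50, rank = self._table[key]
        return BindingResult(peptide=peptide, allele=allele, ic50=ic50,
                             percent_rank=rank, source=self.name)


class NetMHCpanPredictor(BindingPredictor):
    """Subprocess adapter for an installed ``netMHCpan`` binary.

    Raises :class:`PredictorUnavailableError` when the binary is not on PATH;
    there is deliberately no silent fallback to the toy predictor.
    """

    name = "netmhcpan"

    def __init__(self, binary: str = "netMHCpan"):
        self.binary = binary
        self._cache: dict = {}
        if shutil.which(binary) is None:
            raise PredictorUnavailableError(
                f"external predictor binary {binary!r} not found on PATH; "
                "install it or use the 'toy' or 'table:<path>' predictor")

    def predict_one(self, peptide: str, allele: MhcAllele) -> BindingResult:
        _validate_peptide(peptide)
        proc = subprocess.run(
            [self.binary, "-p", "-BA", "-a", allele.serialize()],
            input=peptide + "\n", capture_output=True, text=True, check=True)
        for line in proc.stdout.splitlines():
            parts = line.split()
            if peptide in parts:
                ic50 = float(parts[-2])
                rank = float(parts[-1])
                return BindingResult(peptide=peptide, allele=allele,
                                     ic50=ic50, percent_rank=rank,
                                     source=self.name)
        raise RuntimeError(
            f"could not parse {self.binary} output for {peptide}")


def get_predictor(spec: str) -> BindingPredictor:
    """Resolve a predictor identifier: ``toy``, ``table:<path>``, ``netmhcpan``."""
    if spec == "toy":
        return ToyPredictor()
    if spec.startswith("table:"):
        return TablePredictor(spec.split(":", 1)[1])
    if spec == "netmhcpan":
        return NetMHCpanPredictor()
    raise ConfigurationError(f"unknown binding predictor {spec!r}")


def predict(peptides: Sequence[str], allele: MhcAllele,
            predictor: BindingPredictor | str) -> list[BindingResult]:
    """Score peptides against one allele through a predictor adapter."""
    if isinstance(predictor, str):
        predictor = get_predictor(predictor)
    return predictor.predict(peptides, allele)


def candidate_cutoff(results: Iterable[BindingResult],
                     cutoff_nM: float = DEFAULT_CANDIDATE_CUTOFF_NM,
                     ) -> list[BindingResult]:
    """Keep results with IC50 strictly below the candidate cutoff (500 nM)."""
    return [r for r in results if r.ic50 < cutoff_nM]
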