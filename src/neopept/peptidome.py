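"""Immunopeptidome filtering, normalization and neoepitope flagging.

Identified-peptide lists (peptide-spectrum matches with target/decoy flags)
are filtered to a peptide-level FDR by target-decoy threshold search, then
to the 8-25 aa length window typical of MHC class I elution experiments.
Intensities are normalized per sample by an asymmetric quartile scheme:
log2 transform, subtract the median, then divide positive residuals by
q3 - q2 and negative residuals by q2 - q1, so the median maps to 0, q1 to
-1 and q3 to +1. Finally, retained peptides are cross-referenced against
the mutant long-peptide database and the reference proteome: a neoepitope
call requires the peptide to sit inside a long peptide, cover the mutated
residue, and be absent from the normal proteome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variantdb import LongPeptide, ProteinRecord

DEFAULT_FDR = 0.05
MIN_LENGTH = 8
MAX_LENGTH = 25


class AllDecoysError(ValueError):
    """Every PSM in the input is a decoy; no targets to retain."""


class DegenerateSpreadError(ValueError):
    """Quartile spread is zero; the asymmetric scaling is undefined."""


@dataclass(frozen=True)
class PeptideSpectrumMatch:
    sequence: str
    score: float
    is_decoy: bool = False
    intensity: float | None = None
    sample: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        if self.intensity is not None and self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass(frozen=True)
class NeoepitopeHit:
    sequence: str
    long_peptide: LongPeptide
    covers_mutation: bool
    in_reference: bool
    allele: str | None = None

    def __post_init__(self) -> None:
        if not self.covers_mutation or self.in_reference:
            raise ValueError(
                "a neoepitope hit must cover the mutation and be absent "
                "from the reference proteome"
            )


def fdr_threshold(
    psms: Sequence[PeptideSpectrumMatch], fdr: float = DEFAULT_FDR
) -> float:
    """Smallest score threshold t with #decoys(>=t) / #targets(>=t) <= fdr.

    The search scans the union of observed scores; ties are retained
    together. Returns +inf when no threshold satisfies the bound.
    """
    targets = np.array([p.score for p in psms if not p.is_decoy], dtype=float)
    decoys = np.array([p.score for p in psms if p.is_decoy], dtype=float)
    if targets.size == 0:
        raise AllDecoysError("no target PSMs in input")
    best = np.inf
    for t in np.unique(np.concatenate([targets, decoys])):
        n_targets = int((targets >= t).sum())
        if n_targets == 0:
            continue
        n_decoys = int((decoys >= t).sum())
        if n_decoys / n_targets <= fdr and t < best:
            best = t
    return float(best)


def filter_by_fdr(
    psms: Sequence[PeptideSpectrumMatch], fdr: float = DEFAULT_FDR
) -> list[PeptideSpectrumMatch]:
    """Retain target PSMs scoring at or above the FDR threshold; decoys are
    never returned."""
    t = fdr_threshold(psms, fdr)
    return [p for p in psms if not p.is_decoy and p.score >= t]


def filter_by_length(
    psms: Iterable[PeptideSpectrumMatch],
    min_length: int = MIN_LENGTH,
    max_length: int = MAX_LENGTH,
) -> list[PeptideSpectrumMatch]:
    """Inclusive length window, 8-25 aa by default."""
    return [p for p in psms if min_length <= len(p.sequence) <= max_length]


def normalize_intensities(
    values: Sequence[float], log_transform: bool = True
) -> np.ndarray:
    """Asymmetric quartile normalization of one sample's intensities.

    Values are log2-transformed (disable for pre-logged input), centered on
    the median, then positive residuals are divided by q3 - q2 and negative
    residuals by q2 - q1. Quartiles use linear interpolation on sorted
    values. Fixed points: median -> 0, q1 -> -1, q3 -> +1; values exactly
    at the median map to 0.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError("need at least 4 values to estimate quartiles")
    if log_transform:
        if np.any(arr <= 0):
            raise ValueError("log2 transform requires positive intensities")
        arr = np.log2(arr)
    q1, q2, q3 = np.percentile(arr, [25, 50, 75])
    if q3 == q2 or q2 == q1:
        raise DegenerateSpreadError(
            f"degenerate quartile spread (q1={q1}, q2={q2}, q3={q3})"
        )
    centered = arr - q2
    out = np.where(centered > 0, centered / (q3 - q2), centered / (q2 - q1))
    out[centered == 0] = 0.0
    return out


def flag_neoepitopes(
    retained: Iterable[PeptideSpectrumMatch],
    long_peptides: Sequence[LongPeptide],
    reference: Sequence[ProteinRecord],
) -> list[NeoepitopeHit]:
    """Cross-reference retained peptides against the mutant database.

    A peptide is flagged iff it is a substring of some long peptide with a
    span covering the mutated offset, and it occurs nowhere in the reference
    proteome (mutation-covering peptides that coincidentally match a
    reference substring are not tumor-specific and are excluded).
    Duplicate peptide sequences are reported once.
    """
    ref_blob = "\x00".join(p.sequence for p in reference)
    hits: list[NeoepitopeHit] = []
    seen: set[str] = set()
    for psm in retained:
        seq = psm.sequence
        if psm.is_decoy or seq in seen:
            continue
        match = _find_mutation_covering_parent(seq, long_peptides)
        if match is None:
            continue
        if seq in ref_blob:
            continue
        seen.add(seq)
        hits.append(
            NeoepitopeHit(
                sequence=seq,
                long_peptide=match,
                covers_mutation=True,
                in_reference=False,
            )
        )
    return hits


def _find_mutation_covering_parent(
    seq: str, long_peptides: Sequence[LongPeptide]
) -> LongPeptide | None:
    for lp in long_peptides:
        start = lp.sequence.find(seq)
        while start != -1:
            if start < lp.mutation_offset <= start + len(seq):
                return lp
            start = lp.sequence.find(seq, start + 1)
    return None


def length_distribution(
    psms: Iterable[PeptideSpectrumMatch],
) -> dict[int, int]:
    """Exact histogram of peptide lengths (QC report)."""
    return dict(sorted(Counter(len(p.sequence) for p in psms).items()))


# ---------------------------------------------------------------------------
# PSM table I/O

PSM_COLUMNS = ["sequence", "score", "is_decoy", "intensity", "sample"]


def read_psm_table(path: str | Path) -> list[PeptideSpectrumMatch]:
    df = pd.read_csv(path, sep="\t")
    missing = {"sequence", "score", "is_decoy"} - set(df.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")
    psms = []
    for row in df.itertuples():
        intensity = getattr(row, "intensity", None)
        if intensity is not None and pd.isna(intensity):
            intensity = None
        psms.append(
            PeptideSpectrumMatch(
                sequence=str(row.sequence),
                score=float(row.score),
                is_decoy=bool(row.is_decoy),
                intensity=None if intensity is None else float(intensity),
                sample=str(getattr(row, "sample", "") or ""),
            )
        )
    return psms


def write_psm_table(
    psms: Iterable[PeptideSpectrumMatch], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "sequence": p.sequence,
                "score": p.score,
                "is_decoy": p.is_decoy,
                "intensity": p.intensity,
                "sample": p.sample,
            }
            for p in psms
        ],
        columns=PSM_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def write_hits_table(hits: Iterable[NeoepitopeHit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sequence": h.sequence,
                "long_peptide": h.long_peptide.header,
                "allele": h.allele or "",
            }
            for h in hits
        ],
        columns=["sequence", "long_peptide", "allele"],
    ).to_csv(path, sep="\t", index=False)
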