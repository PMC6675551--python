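"""MHC class I motif scoring, allele assignment, DAI and affinity tiers.

Peptides are scored against per-allele position weight matrices (log-odds
weights per position and residue) for the BALB/c H-2 alleles Kd, Dd and Ld.
A peptide is assigned to the best-scoring allele when it beats the runner-up
by a margin; externally predicted IC50 values (nM) can be injected from a
TSV, and the Differential Agretopic Index (DAI) compares mutant and
wild-type binding on the log-IC50 scale.

The shipped motifs are deliberately simple anchor tables (Kd: Tyr/Phe at P2,
aliphatic C-terminus; Dd: Gly at P2, Pro at P3, hydrophobic C-terminus with
a tolerant P5 secondary anchor; Ld: Pro at P2). They are a transparent
stand-in for a trained affinity predictor, editable via a YAML config
without code change; quantitative IC50s always come from the injection
interface, never from the motif score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

#: label used for the C-terminal (POmega) position in weight tables
OMEGA = "POmega"

DEFAULT_MARGIN = 1.0
DEFAULT_FLOOR = 0.0

#: IC50 tier boundaries in nM, half-open intervals [lo, hi)
DEFAULT_TIERS = (("strong", 50.0), ("intermediate", 500.0), ("weak", 5000.0))


class PeptideLengthError(ValueError):
    """Peptide length outside the motif's accepted range."""


@dataclass(frozen=True)
class AlleleMotif:
    """Position weight table for one MHC allele.

    weights maps a position label ("P1".."P11" or "POmega" for the
    C-terminus) to a residue -> log-odds mapping; unlisted residues weigh 0.
    """

    allele: str
    length_range: tuple[int, int]
    weights: Mapping[str, Mapping[str, float]]
    anchor_positions: frozenset[str] = frozenset()

    def accepts(self, peptide: str) -> bool:
        lo, hi = self.length_range
        return lo <= len(peptide) <= hi


@dataclass(frozen=True)
class BindingPrediction:
    peptide: str
    allele: str
    motif_score: float
    ic50_nm: float | None = None

    def __post_init__(self) -> None:
        if self.ic50_nm is not None and self.ic50_nm <= 0:
            raise ValueError("ic50_nm must be positive when present")


@dataclass(frozen=True)
class DAIRecord:
    """Mutant and wild-type predictions for the same allele and coordinates,
    with their Differential Agretopic Index."""

    mutant: BindingPrediction
    wildtype: BindingPrediction
    dai: float

    def __post_init__(self) -> None:
        if self.mutant.allele != self.wildtype.allele:
            raise ValueError("DAI compares predictions on the same allele")


def score_peptide(peptide: str, motif: AlleleMotif) -> float:
    """Sum of per-position log-odds weights; higher = better motif fit."""
    if not motif.accepts(peptide):
        raise PeptideLengthError(
            f"{motif.allele} accepts lengths {motif.length_range}, "
            f"peptide has {len(peptide)}"
        )
    total = 0.0
    n = len(peptide)
    for i, residue in enumerate(peptide, start=1):
        row = motif.weights.get(f"P{i}")
        if row:
            total += row.get(residue, 0.0)
        if i == n:
            omega_row = motif.weights.get(OMEGA)
            if omega_row:
                total += omega_row.get(residue, 0.0)
    return total


def assign_allele(
    peptide: str,
    motifs: Sequence[AlleleMotif],
    margin: float = DEFAULT_MARGIN,
    floor: float = DEFAULT_FLOOR,
) -> str | None:
    """Best-scoring allele, or None when ambiguous or below the floor.

    The winner must exceed the runner-up by at least ``margin`` and exceed
    the acceptance floor; exact ties resolve to None. Order of the motif
    list does not matter.
    """
    scored = sorted(
        (
            (score_peptide(peptide, m), m.allele)
            for m in motifs
            if m.accepts(peptide)
        ),
        key=lambda t: (-t[0], t[1]),
    )
    if not scored:
        raise PeptideLengthError(
            f"no motif accepts a peptide of length {len(peptide)}"
        )
    best_score, best_allele = scored[0]
    if best_score <= floor:
        return None
    if len(scored) > 1 and best_score - scored[1][0] < margin:
        return None
    return best_allele


def compute_dai(ic50_wt: float, ic50_mut: float) -> float:
    """DAI = ln(IC50_wt) - ln(IC50_mut); positive when the mutation
    improves MHC binding (lower mutant IC50)."""
    if ic50_wt <= 0 or ic50_mut <= 0:
        raise ValueError("IC50 values must be positive")
    return math.log(ic50_wt) - math.log(ic50_mut)


def classify_affinity_tier(
    ic50_nm: float,
    tiers: Sequence[tuple[str, float]] = DEFAULT_TIERS,
) -> str:
    """Conventional IC50 tier: strong (<50 nM), intermediate (<500),
    weak (<5000), very_weak otherwise. Intervals are half-open [lo, hi)."""
    if ic50_nm <= 0:
        raise ValueError("IC50 must be positive")
    for label, upper in tiers:
        if ic50_nm < upper:
            return label
    return "very_weak"


# ---------------------------------------------------------------------------
# Shipped default motifs and config I/O

_DEFAULT_MOTIF_YAML = """\
Kd:
  length_range: [8, 11]
  anchors: [P2, POmega]
  weights:
    P2: {Y: 2.0, F: 1.8}
    POmega: {L: 2.0, I: 1.8, V: 1.6}
Dd:
  length_range: [8, 11]
  anchors: [P2, P3, POmega]
  weights:
    P2: {G: 2.0}
    P3: {P: 1.5}
    P5: {F: 1.0, R: 0.5, I: 0.5, G: 0.3}
    POmega: {L: 2.0, I: 1.8, F: 1.8}
Ld:
  length_range: [8, 11]
  anchors: [P2, POmega]
  weights:
    P2: {P: 2.0}
    POmega: {F: 2.0, L: 1.8, M: 1.6}
"""


def motifs_from_mapping(data: Mapping[str, Mapping]) -> list[AlleleMotif]:
    motifs = []
    for allele, spec in data.items():
        motifs.append(
            AlleleMotif(
                allele=allele,
                length_range=tuple(spec["length_range"]),
                weights={
                    pos: dict(row) for pos, row in spec["weights"].items()
                },
                anchor_positions=frozenset(spec.get("anchors", ())),
            )
        )
    return motifs


def load_motifs(path: str | Path | None = None) -> list[AlleleMotif]:
    """Load allele motifs from a YAML config; with no path, the shipped
    H-2 Kd/Dd/Ld defaults."""
    if path is None:
        data = yaml.safe_load(_DEFAULT_MOTIF_YAML)
    else:
        data = yaml.safe_load(Path(path).read_text())
    return motifs_from_mapping(data)


def default_motifs() -> list[AlleleMotif]:
    return load_motifs(None)


def read_ic50_table(path: str | Path) -> dict[tuple[str, str], float]:
    """External IC50 injection: TSV with columns peptide, allele, ic50_nm,
    keyed by (peptide, allele)."""
    df = pd.read_csv(path, sep="\t")
    required = {"peptide", "allele", "ic50_nm"}
    if not required <= set(df.columns):
        raise ValueError(f"IC50 table needs columns {sorted(required)}")
    table: dict[tuple[str, str], float] = {}
    for row in df.itertuples():
        ic50 = float(row.ic50_nm)
        if ic50 <= 0:
            raise ValueError(f"non-positive IC50 for {row.peptide}")
        table[(str(row.peptide), str(row.allele))] = ic50
    return table


def predict(
    peptide: str,
    motifs: Sequence[AlleleMotif],
    ic50_table: Mapping[tuple[str, str], float] | None = None,
    margin: float = DEFAULT_MARGIN,
    floor: float = DEFAULT_FLOOR,
) -> BindingPrediction | None:
    """Assign an allele and attach any externally supplied IC50."""
    allele = assign_allele(peptide, motifs, margin=margin, floor=floor)
    if allele is None:
        return None
    motif = next(m for m in motifs if m.allele == allele)
    ic50 = None
    if ic50_table is not None:
        ic50 = ic50_table.get((peptide, allele))
    return BindingPrediction(
        peptide=peptide,
        allele=allele,
        motif_score=score_peptide(peptide, motif),
        ic50_nm=ic50,
    )


def dai_record(
    mutant: BindingPrediction, wildtype: BindingPrediction
) -> DAIRecord:
    if mutant.ic50_nm is None or wildtype.ic50_nm is None:
        raise ValueError("DAI needs IC50 values on both predictions")
    return DAIRecord(
        mutant=mutant,
        wildtype=wildtype,
        dai=compute_dai(wildtype.ic50_nm, mutant.ic50_nm),
    )
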