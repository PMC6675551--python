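"""Mutant search-space construction from somatic amino-acid variants.

Somatic single-nucleotide variants, already translated to protein
coordinates, are applied to a reference proteome to build mutation-centered
"long peptide" windows (up to ``2*flank + 1`` residues, 31 aa by default).
The long peptides are concatenated to the reference proteome to form the
search database used for immunopeptidome identification, and each window is
expanded into the short (8-11-mer) mutation-covering candidate epitopes that
are scored for MHC binding downstream.

Positions are 1-based and inclusive throughout, matching the immunology
P1..POmega convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: default residues flanking the mutation on each side; 15 gives the
#: conventional 31-aa maximum window (15 + 1 + 15)
DEFAULT_FLANK = 15

#: candidate epitope lengths enumerated from each long peptide
DEFAULT_EPITOPE_LENGTHS = (8, 9, 10, 11)


class ReferenceMismatchError(ValueError):
    """The variant's stated reference residue disagrees with the proteome."""


class PositionOutOfRangeError(IndexError):
    """The variant position falls outside the protein sequence."""


@dataclass(frozen=True)
class ProteinRecord:
    """A reference protein: identifier plus canonical amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or not self.sequence:
            raise ValueError("protein id and sequence must be non-empty")

    @property
    def is_canonical(self) -> bool:
        return set(self.sequence) <= CANONICAL_AA


@dataclass(frozen=True)
class SomaticVariant:
    """One amino-acid substitution with coverage and expression annotations.

    position is 1-based; tpm is transcripts per million for the host gene.
    """

    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str
    coverage: int = 0
    tpm: float = 0.0

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError(
                f"variant {self.protein_id}:{self.position} is synonymous "
                f"({self.ref_aa}->{self.alt_aa})"
            )
        if self.position < 1:
            raise PositionOutOfRangeError(
                f"position must be >= 1, got {self.position}"
            )
        if self.coverage < 0 or self.tpm < 0:
            raise ValueError("coverage and tpm must be non-negative")


@dataclass(frozen=True)
class LongPeptide:
    """A mutation-centered window of the mutated protein.

    mutation_offset is the 1-based index of the mutant residue within the
    window; flank records the requested flanking length (the realized window
    may be shorter at protein termini).
    """

    sequence: str
    source_variant: SomaticVariant
    mutation_offset: int
    flank: int

    def __post_init__(self) -> None:
        if not 1 <= self.mutation_offset <= len(self.sequence):
            raise ValueError("mutation_offset outside window")
        if len(self.sequence) > 2 * self.flank + 1:
            raise ValueError("window longer than 2*flank+1")
        if self.sequence[self.mutation_offset - 1] != self.source_variant.alt_aa:
            raise ValueError("window does not carry the mutant residue")

    @property
    def header(self) -> str:
        v = self.source_variant
        return f"neo|{v.protein_id}|p.{v.ref_aa}{v.position}{v.alt_aa}"


@dataclass(frozen=True)
class CandidateEpitope:
    """A short mutation-covering k-mer paired with its WT counterpart."""

    sequence: str
    parent: LongPeptide
    covers_mutation: bool
    wt_counterpart: str

    def __post_init__(self) -> None:
        if not self.covers_mutation:
            raise ValueError("only mutation-covering candidates are emitted")
        diffs = sum(a != b for a, b in zip(self.sequence, self.wt_counterpart))
        if len(self.sequence) != len(self.wt_counterpart) or diffs != 1:
            raise ValueError(
                "WT counterpart must differ at exactly one position"
            )


def apply_variant(protein: ProteinRecord, variant: SomaticVariant) -> str:
    """Return the protein sequence with the substitution applied.

    Raises ReferenceMismatchError when the stated reference residue does not
    match the proteome (silent skips would corrupt downstream FDR
    denominators, so mismatches are loud), and PositionOutOfRangeError for
    positions beyond the protein.
    """
    if variant.protein_id != protein.id:
        raise ValueError(
            f"variant targets {variant.protein_id!r}, protein is {protein.id!r}"
        )
    if variant.position > len(protein.sequence):
        raise PositionOutOfRangeError(
            f"position {variant.position} beyond {protein.id} "
            f"(length {len(protein.sequence)})"
        )
    idx = variant.position - 1
    found = protein.sequence[idx]
    if found != variant.ref_aa:
        raise ReferenceMismatchError(
            f"{protein.id} position {variant.position}: reference has "
            f"{found}, variant states {variant.ref_aa}"
        )
    return protein.sequence[:idx] + variant.alt_aa + protein.sequence[idx + 1:]


def build_long_peptide(
    protein: ProteinRecord,
    variant: SomaticVariant,
    flank: int = DEFAULT_FLANK,
) -> LongPeptide:
    """Cut the mutation-centered window out of the mutated protein.

    The window spans positions max(1, p-flank)..min(L, p+flank) of the
    mutated sequence, truncated only at protein termini.
    """
    mutated = apply_variant(protein, variant)
    start = max(1, variant.position - flank)
    stop = min(len(mutated), variant.position + flank)
    return LongPeptide(
        sequence=mutated[start - 1: stop],
        source_variant=variant,
        mutation_offset=variant.position - start + 1,
        flank=flank,
    )


def enumerate_candidates(
    long_peptide: LongPeptide,
    lengths: Iterable[int] = DEFAULT_EPITOPE_LENGTHS,
) -> list[CandidateEpitope]:
    """All k-mers of the requested lengths whose span covers the mutation.

    Each candidate is paired with its same-coordinates wild-type k-mer.
    Windows shorter than every requested length yield an empty list.
    """
    window = long_peptide.sequence
    m = long_peptide.mutation_offset - 1  # 0-based
    wt_window = (
        window[:m] + long_peptide.source_variant.ref_aa + window[m + 1:]
    )
    out: list[CandidateEpitope] = []
    for k in sorted(set(lengths)):
        if k < 1 or k > len(window):
            continue
        for start in range(max(0, m - k + 1), min(m, len(window) - k) + 1):
            out.append(
                CandidateEpitope(
                    sequence=window[start: start + k],
                    parent=long_peptide,
                    covers_mutation=True,
                    wt_counterpart=wt_window[start: start + k],
                )
            )
    return out


def build_long_peptides(
    proteome: Sequence[ProteinRecord],
    variants: Iterable[SomaticVariant],
    flank: int = DEFAULT_FLANK,
) -> list[LongPeptide]:
    """Windows for every variant; proteins with nonstandard residues are
    excluded (logged), duplicate windows from distinct variants retained."""
    by_id = {p.id: p for p in proteome}
    out: list[LongPeptide] = []
    for variant in variants:
        protein = by_id.get(variant.protein_id)
        if protein is None:
            raise KeyError(f"unknown protein {variant.protein_id!r}")
        if not protein.is_canonical:
            logger.warning(
                "protein %s contains nonstandard residues; skipped",
                protein.id,
            )
            continue
        out.append(build_long_peptide(protein, variant, flank=flank))
    return out


# ---------------------------------------------------------------------------
# FASTA and SNV-table I/O


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def write_search_database(
    reference: Sequence[ProteinRecord],
    long_peptides: Sequence[LongPeptide],
    path: str | Path,
) -> None:
    """Write the concatenated search database: reference entries first, then
    one entry per long peptide with a ``neo|<protein>|p.<ref><pos><alt>``
    header. Round-trips through :func:`read_fasta`."""
    records = list(reference) + [
        ProteinRecord(id=lp.header, sequence=lp.sequence)
        for lp in long_peptides
    ]
    write_fasta(records, path)


def is_neo_header(record_id: str) -> bool:
    return record_id.startswith("neo|")


def parse_neo_header(record_id: str) -> tuple[str, int, str, str]:
    """Split ``neo|<protein_id>|p.<ref><pos><alt>`` into its fields."""
    _, protein_id, hgvs = record_id.split("|")
    body = hgvs.removeprefix("p.")
    return protein_id, int(body[1:-1]), body[0], body[-1]


SNV_COLUMNS = ["protein_id", "position", "ref_aa", "alt_aa", "coverage", "tpm"]


def read_snv_table(path: str | Path) -> list[SomaticVariant]:
    """Load a TSV of somatic variants (columns protein_id, position, ref_aa,
    alt_aa, coverage, tpm)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SNV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SNV table missing columns: {sorted(missing)}")
    return [
        SomaticVariant(
            protein_id=str(row.protein_id),
            position=int(row.position),
            ref_aa=str(row.ref_aa),
            alt_aa=str(row.alt_aa),
            coverage=int(row.coverage),
            tpm=float(row.tpm),
        )
        for row in df.itertuples()
    ]


def write_snv_table(variants: Iterable[SomaticVariant], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "protein_id": v.protein_id,
                "position": v.position,
                "ref_aa": v.ref_aa,
                "alt_aa": v.alt_aa,
                "coverage": v.coverage,
                "tpm": v.tpm,
            }
            for v in variants
        ],
        columns=SNV_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
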