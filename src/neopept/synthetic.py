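"""Synthetic inputs with the statistical structure the pipeline assumes.

Raw immunopeptidomics and sequencing data for the original tumor-model
study are not deposited, so every pipeline stage is exercised on generated
inputs: a random proteome with planted somatic variants, PSM lists with
separated target/decoy score distributions and log-normal intensities,
Gaussian co-eluting heavy/light PRM peaks, logistic tumor growth curves
with rejection/stabilization phenotypes, and idealized extended-peptide
coordinate sets for the structural metrics.

A single global seed fans out to independent per-generator streams via
``numpy.random.SeedSequence.spawn``-style keying, so changing one
generator's draw count never perturbs another's output. Each generator
returns ground truth alongside its data; the CLI writes truth sidecars
next to every generated file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .peptidome import PeptideSpectrumMatch
from .prm import ChromatogramTrace
from .structure import (
    ELEMENT_RADII,
    AtomRecord,
    PmhcModel,
)
from .tumor_control import GrowthCurve
from .variantdb import (
    CANONICAL_AA,
    LongPeptide,
    ProteinRecord,
    SomaticVariant,
    build_long_peptides,
    enumerate_candidates,
)

AA = sorted(CANONICAL_AA)

#: three-letter residue names, for writing toy models in PDB format
THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generators.

    Defaults emulate a small-scale version of a murine neoepitope screen:
    a few hundred proteins, tens of somatic variants, PSM scores with
    well-separated target and decoy distributions (Andromeda-like score
    scale), log-normal elution intensities, sharp co-eluting PRM peaks,
    and 5-mouse treatment groups observed every third day for 24 days with
    logistic tumor growth reaching ~15 mm in controls.
    """

    seed: int = 0
    # proteome / variants
    n_proteins: int = 200
    protein_length: tuple[int, int] = (80, 400)
    n_variants: int = 40
    # PSM lists
    n_target_psms: int = 300
    n_decoy_psms: int = 300
    n_planted_neoepitopes: int = 10
    target_score: tuple[float, float] = (80.0, 10.0)  # mean, sd
    decoy_score: tuple[float, float] = (30.0, 10.0)
    log_intensity: tuple[float, float] = (20.0, 2.0)  # log2 mean, sd
    # PRM traces
    rt_apex: float = 30.0  # minutes
    peak_width: float = 0.15  # Gaussian sigma, minutes
    rt_window: float = 2.0  # half-width of the scheduled window
    rt_step: float = 0.02
    peak_noise: float = 0.01  # relative intensity noise
    n_fragments: int = 6
    # growth curves
    group_size: int = 5
    days: tuple[int, ...] = tuple(range(0, 25, 3))
    control_max_mm: float = 15.0
    growth_rate: float = 0.35
    growth_midpoint: float = 12.0
    growth_noise_sd: float = 0.4
    rejection_fraction: float = 0.0
    # toy structures
    ca_spacing: float = 3.8


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    """Independent, reproducible stream per generator."""
    root = np.random.SeedSequence(config.seed)
    key = int.from_bytes(stream.encode(), "little") % (2**32)
    return np.random.default_rng(np.random.SeedSequence([config.seed, key]))


# ---------------------------------------------------------------------------
# Proteome and variants


def gen_proteome(config: SimConfig) -> list[ProteinRecord]:
    rng = _rng(config, "proteome")
    lo, hi = config.protein_length
    records = []
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(AA, size=length))
        records.append(ProteinRecord(id=f"SYN{i:04d}", sequence=seq))
    return records


def gen_variants(
    proteome: Sequence[ProteinRecord], config: SimConfig
) -> list[SomaticVariant]:
    """Variants satisfying the reference-match invariant by construction."""
    rng = _rng(config, "variants")
    variants = []
    for _ in range(config.n_variants):
        protein = proteome[int(rng.integers(len(proteome)))]
        position = int(rng.integers(1, len(protein.sequence) + 1))
        ref = protein.sequence[position - 1]
        alt = str(rng.choice([a for a in AA if a != ref]))
        variants.append(
            SomaticVariant(
                protein_id=protein.id,
                position=position,
                ref_aa=ref,
                alt_aa=alt,
                coverage=int(rng.integers(10, 200)),
                tpm=float(np.round(rng.lognormal(2.0, 1.5), 3)),
            )
        )
    return variants


# ---------------------------------------------------------------------------
# PSM lists


def gen_psm_list(
    long_peptides: Sequence[LongPeptide],
    proteome: Sequence[ProteinRecord],
    config: SimConfig,
) -> tuple[list[PeptideSpectrumMatch], pd.DataFrame]:
    """PSMs with planted neoepitopes, reference targets and decoys.

    Returns the PSM list plus a ground-truth table (sequence, kind) with
    kind in {neoepitope, reference, decoy}.
    """
    rng = _rng(config, "psms")
    t_mu, t_sd = config.target_score
    d_mu, d_sd = config.decoy_score
    li_mu, li_sd = config.log_intensity

    psms: list[PeptideSpectrumMatch] = []
    truth_rows: list[dict] = []

    def add(seq: str, score: float, is_decoy: bool, kind: str) -> None:
        psms.append(
            PeptideSpectrumMatch(
                sequence=seq,
                score=float(score),
                is_decoy=is_decoy,
                intensity=float(2.0 ** rng.normal(li_mu, li_sd)),
                sample="sim",
            )
        )
        truth_rows.append({"sequence": seq, "kind": kind})

    # planted neoepitopes: mutation-covering 8-11-mers from long peptides
    planted = 0
    order = rng.permutation(len(long_peptides))
    ref_blob = "\x00".join(p.sequence for p in proteome)
    for idx in order:
        if planted >= config.n_planted_neoepitopes:
            break
        candidates = [
            c for c in enumerate_candidates(long_peptides[idx])
            if c.sequence not in ref_blob
        ]
        if not candidates:
            continue
        pick = candidates[int(rng.integers(len(candidates)))]
        add(pick.sequence, rng.normal(t_mu, t_sd), False, "neoepitope")
        planted += 1

    # ordinary targets: substrings of the reference proteome
    n_ref = max(0, config.n_target_psms - planted)
    for _ in range(n_ref):
        protein = proteome[int(rng.integers(len(proteome)))]
        k = int(rng.integers(8, 12))
        start = int(rng.integers(0, len(protein.sequence) - k + 1))
        add(
            protein.sequence[start: start + k],
            rng.normal(t_mu, t_sd),
            False,
            "reference",
        )

    # decoys: random sequences scored from the lower distribution
    for _ in range(config.n_decoy_psms):
        k = int(rng.integers(8, 12))
        seq = "".join(rng.choice(AA, size=k))
        add(seq, rng.normal(d_mu, d_sd), True, "decoy")

    truth = pd.DataFrame(truth_rows, columns=["sequence", "kind"])
    return psms, truth


# ---------------------------------------------------------------------------
# PRM traces


def gen_prm_traces(
    config: SimConfig,
    apex_shift: float = 0.0,
    light_scale: float = 1.0,
) -> tuple[dict[str, ChromatogramTrace], dict[str, ChromatogramTrace]]:
    """Gaussian heavy/light fragment peaks on a shared retention-time grid.

    The heavy channel peaks at ``rt_apex``; the light channel at
    ``rt_apex + apex_shift`` and scaled by ``light_scale`` (0 simulates a
    missing endogenous peptide). Returns (light, heavy) keyed by fragment.
    """
    rng = _rng(config, "prm")
    times = np.arange(
        config.rt_apex - config.rt_window,
        config.rt_apex + config.rt_window + config.rt_step / 2,
        config.rt_step,
    )
    light: dict[str, ChromatogramTrace] = {}
    heavy: dict[str, ChromatogramTrace] = {}
    for f in range(config.n_fragments):
        name = f"y{f + 1}+1"
        amplitude = float(rng.uniform(0.3, 1.0)) * 1e6
        shape_h = amplitude * np.exp(
            -0.5 * ((times - config.rt_apex) / config.peak_width) ** 2
        )
        shape_l = light_scale * amplitude * np.exp(
            -0.5
            * ((times - config.rt_apex - apex_shift) / config.peak_width) ** 2
        )
        noise_h = 1 + config.peak_noise * rng.standard_normal(times.size)
        noise_l = 1 + config.peak_noise * rng.standard_normal(times.size)
        heavy[name] = ChromatogramTrace(
            times=times,
            intensities=np.clip(shape_h * noise_h, 0, None),
            channel="heavy",
        )
        light[name] = ChromatogramTrace(
            times=times,
            intensities=np.clip(shape_l * noise_l, 0, None),
            channel="light",
        )
    return light, heavy


# ---------------------------------------------------------------------------
# Growth curves


def _logistic(t: np.ndarray, top: float, rate: float, mid: float) -> np.ndarray:
    return top / (1.0 + np.exp(-rate * (t - mid)))


def gen_growth_curves(
    config: SimConfig,
    groups: Mapping[str, float] | None = None,
) -> dict[str, list[GrowthCurve]]:
    """Logistic growth per mouse with rejection phenotypes.

    ``groups`` maps group label -> rejection fraction (probability that a
    mouse fully and durably rejects the tumor); default is a control group
    growing in every mouse plus one vaccinated group at the configured
    rejection fraction. Non-rejecting mice follow noisy logistic growth;
    rejecting mice show a complete response with no palpable tumor at any
    measurement.
    """
    rng = _rng(config, "growth")
    if groups is None:
        groups = {
            "control": 0.0,
            "vaccinated": config.rejection_fraction,
        }
    days = np.asarray(config.days, dtype=float)
    out: dict[str, list[GrowthCurve]] = {}
    for group, reject_frac in groups.items():
        curves = []
        for m in range(config.group_size):
            rejects = bool(rng.random() < reject_frac)
            top = config.control_max_mm * float(rng.uniform(0.85, 1.15))
            if rejects:
                diam = np.zeros_like(days)
            else:
                base = _logistic(
                    days, top, config.growth_rate, config.growth_midpoint
                )
                noise = rng.normal(0.0, config.growth_noise_sd, size=days.size)
                diam = np.clip(
                    base + np.where(base > 0, noise, 0.0), 0.0, None
                )
            curves.append(
                GrowthCurve(
                    mouse_id=f"{group}-{m + 1}",
                    group=group,
                    days=days,
                    diameters=diam,
                )
            )
        out[group] = curves
    return out


def rejection_curve(config: SimConfig) -> GrowthCurve:
    """An idealized complete durable rejection: undetectable at every
    post-challenge measurement."""
    days = np.asarray(config.days, dtype=float)
    return GrowthCurve(
        mouse_id="rejector",
        group="vaccinated",
        days=days,
        diameters=np.zeros_like(days),
    )


def linear_control_curve(
    config: SimConfig, final_mm: float = 15.0
) -> GrowthCurve:
    """A control mean growing linearly from 0 to ``final_mm``."""
    days = np.asarray(config.days, dtype=float)
    return GrowthCurve(
        mouse_id="<control-mean>",
        group="control",
        days=days,
        diameters=final_mm * days / days[-1],
    )


# ---------------------------------------------------------------------------
# Toy peptide-MHC models


def _extended_peptide_atoms(
    peptide: str, chain: str, spacing: float, offset: np.ndarray
) -> list[AtomRecord]:
    """Idealized extended chain: per residue N, CA, C, O (and CB except
    glycine) laid out along the x axis."""
    atoms = []
    for i, aa in enumerate(peptide):
        x0 = i * spacing
        res = THREE_LETTER[aa]
        positions = {
            "N": (x0 - 1.2, 0.4, 0.0),
            "CA": (x0, 0.0, 0.0),
            "C": (x0 + 1.2, 0.4, 0.0),
            "O": (x0 + 1.2, 1.6, 0.0),
        }
        if aa != "G":
            positions["CB"] = (x0, -0.8, 1.2)
        for name, xyz in positions.items():
            element = name[0]
            atoms.append(
                AtomRecord(
                    name=name,
                    element=element,
                    res_name=res,
                    res_seq=i + 1,
                    chain_id=chain,
                    xyz=tuple(float(v) for v in np.asarray(xyz) + offset),
                    radius=ELEMENT_RADII[element],
                )
            )
    return atoms


def gen_toy_pmhc(
    peptide: str,
    config: SimConfig,
    perturbation_sd: float = 0.0,
    mhc_length: int = 20,
) -> tuple[PmhcModel, PmhcModel]:
    """A reference model and a peptide-perturbed copy.

    The "MHC" chain A is an idealized extended poly-alanine scaffold below
    the peptide chain C; the perturbed copy displaces every peptide atom by
    isotropic Gaussian noise of the given sd while the MHC is untouched, so
    MHC-frame superposition is exact and the peptide RMSD is driven only by
    the injected perturbation.
    """
    if not 8 <= len(peptide) <= 11:
        raise ValueError("toy models cover 8-11-mer peptides")
    rng = _rng(config, "structure")
    mhc = _extended_peptide_atoms(
        "A" * mhc_length, "A", config.ca_spacing, np.array([0.0, -8.0, 0.0])
    )
    pep = _extended_peptide_atoms(
        peptide, "C", config.ca_spacing, np.zeros(3)
    )
    reference = PmhcModel(
        atoms=tuple(mhc + pep), peptide_chain="C", mhc_chain="A"
    )
    moved = []
    for a in reference.atoms:
        if a.chain_id == "C" and perturbation_sd > 0:
            shift = rng.normal(0.0, perturbation_sd, size=3)
            moved.append(
                replace(
                    a,
                    xyz=tuple(float(v) for v in np.asarray(a.xyz) + shift),
                )
            )
        else:
            moved.append(a)
    perturbed = PmhcModel(
        atoms=tuple(moved), peptide_chain="C", mhc_chain="A"
    )
    return reference, perturbed
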