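"""Structural post-metrics on peptide-MHC models.

Given WT and mutant peptide-MHC model coordinates (standard PDB format),
this module computes the metrics used to compare the two presentations:

* peptide RMSD after superposing the two models on the MHC backbone (the
  peptide never participates in the fit, so the RMSD measures how much the
  peptide moved within the groove);
* solvent-accessible surface area by Shrake-Rupley sphere sampling with a
  1.4 A water probe;
* the peptide's exposed hydrophobic surface (SASA summed over apolar atoms:
  carbons and sulfurs not covalently bonded to N or O, bonds inferred from
  heavy-atom distances);
* salt bridges between basic side-chain nitrogens and acidic side-chain
  oxygens within a distance cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

#: van der Waals radii (A) per element; the table is configurable
ELEMENT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
DEFAULT_RADIUS = 1.70

PROBE_RADIUS = 1.4
DEFAULT_SASA_POINTS = 960
BACKBONE_ATOMS = ("N", "CA", "C", "O")
BOND_DISTANCE = 1.9  # heavy-atom pairs closer than this are bonded
SALT_BRIDGE_CUTOFF = 4.0

#: charged-group atoms for salt-bridge detection
BASIC_ATOMS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
ACIDIC_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

#: residues treated as water / solvent when stripping heteroatoms
WATER_NAMES = {"HOH", "WAT", "DOD"}


class PdbFormatError(ValueError):
    """A malformed ATOM/HETATM record; the message names the line."""


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    xyz: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in self.xyz):
            raise ValueError("non-finite coordinates")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class PmhcModel:
    """A peptide-MHC complex: atom list plus the two chain assignments."""

    atoms: tuple[AtomRecord, ...]
    peptide_chain: str
    mhc_chain: str

    def chain(self, chain_id: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.chain_id == chain_id]

    def coords(self, atoms: Iterable[AtomRecord] | None = None) -> np.ndarray:
        pool = self.atoms if atoms is None else list(atoms)
        return np.array([a.xyz for a in pool], dtype=float)

    def peptide_residues(self) -> list[tuple[int, str, list[AtomRecord]]]:
        """Peptide residues in sequence order: (res_seq, res_name, atoms)."""
        by_res: dict[int, list[AtomRecord]] = {}
        names: dict[int, str] = {}
        for a in self.chain(self.peptide_chain):
            by_res.setdefault(a.res_seq, []).append(a)
            names[a.res_seq] = a.res_name
        return [(i, names[i], by_res[i]) for i in sorted(by_res)]


@dataclass(frozen=True)
class RmsdReport:
    selection: str  # 'backbone' | 'common_heavy'
    n_atoms: int
    rmsd: float


@dataclass(frozen=True)
class SasaReport:
    per_atom: dict[int, float]  # atom index in model -> area (A^2)
    peptide_total: float
    peptide_hydrophobic: float


@dataclass(frozen=True)
class SaltBridge:
    basic_residue: str  # e.g. "ARG 5 C"
    acidic_residue: str
    distance: float


# ---------------------------------------------------------------------------
# PDB reading / writing


def _parse_atom_line(line: str, lineno: int) -> AtomRecord | None:
    try:
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or " "
        res_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PdbFormatError(
            f"malformed ATOM/HETATM record at line {lineno}: {line.rstrip()!r}"
        ) from exc
    if not element:
        # fall back to the atom-name convention: first alphabetic character
        stripped = name.lstrip("0123456789")
        element = stripped[:1].upper()
    if not element:
        raise PdbFormatError(f"cannot infer element at line {lineno}")
    return AtomRecord(
        name=name,
        element=element,
        res_name=res_name,
        res_seq=res_seq,
        chain_id=chain_id,
        xyz=(x, y, z),
        radius=ELEMENT_RADII.get(element, DEFAULT_RADIUS),
    )


def read_pdb(
    path: str | Path,
    peptide_chain: str = "C",
    mhc_chain: str = "A",
    keep_het: bool = False,
    keep_hydrogens: bool = False,
) -> PmhcModel:
    """Parse a fixed-column PDB file into a model.

    Only the first MODEL is read; waters and heteroatoms are dropped by
    default. Malformed ATOM records raise PdbFormatError naming the line.
    """
    atoms: list[AtomRecord] = []
    in_first_model = True
    seen_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line[:6].strip()
            if tag == "MODEL":
                if seen_model:
                    break
                seen_model = True
                continue
            if tag == "ENDMDL":
                break
            if tag not in ("ATOM", "HETATM"):
                continue
            if tag == "HETATM" and not keep_het:
                continue
            atom = _parse_atom_line(line, lineno)
            if atom.res_name in WATER_NAMES:
                continue
            if atom.element == "H" and not keep_hydrogens:
                continue
            atoms.append(atom)
    return PmhcModel(
        atoms=tuple(atoms), peptide_chain=peptide_chain, mhc_chain=mhc_chain
    )


def write_pdb(model: PmhcModel, path: str | Path) -> None:
    """Write ATOM records in fixed-column PDB format (one model)."""
    with open(path, "w") as fh:
        for i, a in enumerate(model.atoms, start=1):
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            fh.write(
                f"ATOM  {i:5d} {name}{'':1s}{a.res_name:>3s} "
                f"{a.chain_id}{a.res_seq:4d}    "
                f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Superposition and RMSD


def _kabsch_transform(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[Rotation, np.ndarray, np.ndarray]:
    """Least-squares rotation + translation mapping mobile onto target."""
    mob_center = mobile.mean(axis=0)
    tgt_center = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tgt_center, mobile - mob_center)
    return rot, mob_center, tgt_center


def superpose_on_mhc(
    mobile: PmhcModel, target: PmhcModel
) -> PmhcModel:
    """Rigidly transform ``mobile`` so its MHC backbone best fits the
    target's; the peptide is carried along but excluded from the fit."""
    mob_bb = [
        a for a in mobile.chain(mobile.mhc_chain) if a.name in BACKBONE_ATOMS
    ]
    tgt_bb = [
        a for a in target.chain(target.mhc_chain) if a.name in BACKBONE_ATOMS
    ]
    if len(mob_bb) != len(tgt_bb) or not mob_bb:
        raise ValueError(
            "MHC backbones must have matching atom counts for superposition"
        )
    rot, mob_center, tgt_center = _kabsch_transform(
        np.array([a.xyz for a in mob_bb]), np.array([a.xyz for a in tgt_bb])
    )
    moved = []
    for a in mobile.atoms:
        new_xyz = rot.apply(np.asarray(a.xyz) - mob_center) + tgt_center
        moved.append(replace(a, xyz=tuple(float(v) for v in new_xyz)))
    return replace(mobile, atoms=tuple(moved))


def _select_peptide_pairs(
    model_a: PmhcModel, model_b: PmhcModel, selection: str
) -> tuple[np.ndarray, np.ndarray]:
    res_a = model_a.peptide_residues()
    res_b = model_b.peptide_residues()
    if len(res_a) != len(res_b):
        raise ValueError(
            f"peptide lengths differ: {len(res_a)} vs {len(res_b)}"
        )
    xa, xb = [], []
    for (_, _, atoms_a), (_, _, atoms_b) in zip(res_a, res_b):
        map_a = {a.name: a for a in atoms_a if a.element != "H"}
        map_b = {b.name: b for b in atoms_b if b.element != "H"}
        if selection == "backbone":
            names = [n for n in BACKBONE_ATOMS if n in map_a and n in map_b]
        elif selection == "common_heavy":
            names = sorted(set(map_a) & set(map_b))
        else:
            raise ValueError("selection must be 'backbone' or 'common_heavy'")
        for n in names:
            xa.append(map_a[n].xyz)
            xb.append(map_b[n].xyz)
    if not xa:
        raise ValueError("empty atom selection")
    return np.array(xa), np.array(xb)


def peptide_rmsd(
    model_a: PmhcModel,
    model_b: PmhcModel,
    selection: str = "backbone",
    superpose: bool = True,
) -> RmsdReport:
    """RMSD over matched peptide atoms after MHC-frame superposition.

    No re-fitting is done on the peptide itself, so the value reflects
    peptide movement within the MHC groove.
    """
    if superpose:
        model_b = superpose_on_mhc(model_b, model_a)
    xa, xb = _select_peptide_pairs(model_a, model_b, selection)
    rmsd = float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))
    return RmsdReport(selection=selection, n_atoms=len(xa), rmsd=rmsd)


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    model: PmhcModel,
    probe: float = PROBE_RADIUS,
    n_points: int = DEFAULT_SASA_POINTS,
) -> SasaReport:
    """Shrake-Rupley solvent-accessible surface area, per atom.

    Each atom's extended sphere (vdW + probe radius) is sampled with a
    golden-spiral lattice; a sample point is accessible when it lies
    outside every neighboring atom's extended sphere. Area = accessible
    fraction x 4 pi (r + probe)^2.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for a stable estimate")
    coords = model.coords()
    radii = np.array([a.radius for a in model.atoms]) + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * radii.max()

    per_atom: dict[int, float] = {}
    for i, (center, r) in enumerate(zip(coords, radii)):
        pts = center + r * unit
        neighbors = [
            j for j in tree.query_ball_point(center, r + radii.max())
            if j != i
            and np.linalg.norm(coords[j] - center) < r + radii[j]
        ]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            accessible &= (
                np.linalg.norm(pts - coords[j], axis=1) >= radii[j]
            )
        per_atom[i] = float(accessible.mean() * 4.0 * math.pi * r * r)

    pep_idx = [
        i for i, a in enumerate(model.atoms)
        if a.chain_id == model.peptide_chain
    ]
    hydro_idx = set(_apolar_atom_indices(model))
    peptide_total = sum(per_atom[i] for i in pep_idx)
    peptide_hydro = sum(per_atom[i] for i in pep_idx if i in hydro_idx)
    return SasaReport(
        per_atom=per_atom,
        peptide_total=peptide_total,
        peptide_hydrophobic=peptide_hydro,
    )


def _apolar_atom_indices(model: PmhcModel) -> list[int]:
    """Indices of C/S atoms with no covalent N/O neighbor (distance rule)."""
    coords = model.coords()
    tree = cKDTree(coords)
    out = []
    for i, a in enumerate(model.atoms):
        if a.element not in ("C", "S"):
            continue
        polar_neighbor = False
        for j in tree.query_ball_point(coords[i], BOND_DISTANCE):
            if j != i and model.atoms[j].element in ("N", "O"):
                polar_neighbor = True
                break
        if not polar_neighbor:
            out.append(i)
    return out


def hydrophobic_exposed_area(
    model: PmhcModel,
    chain: str | None = None,
    probe: float = PROBE_RADIUS,
    n_points: int = DEFAULT_SASA_POINTS,
) -> float:
    """Exposed hydrophobic surface (A^2) of a chain in the full-complex
    context: SASA summed over its apolar atoms (C/S not bonded to N/O)."""
    chain = chain or model.peptide_chain
    report = sasa(model, probe=probe, n_points=n_points)
    apolar = set(_apolar_atom_indices(model))
    return sum(
        report.per_atom[i]
        for i, a in enumerate(model.atoms)
        if a.chain_id == chain and i in apolar
    )


def relative_area_change(area_wt: float, area_mut: float) -> float:
    """Relative change (A_mut - A_wt) / A_wt of an exposed surface."""
    if area_wt <= 0:
        raise ValueError("WT area must be positive")
    return (area_mut - area_wt) / area_wt


# ---------------------------------------------------------------------------
# Salt bridges


def detect_salt_bridges(
    model: PmhcModel,
    cutoff: float = SALT_BRIDGE_CUTOFF,
    include_his: bool = False,
    include_termini: bool = True,
) -> list[SaltBridge]:
    """Basic-N / acidic-O contacts within the cutoff, one record per
    residue pair at the minimum inter-group distance."""
    basic_table = dict(BASIC_ATOMS)
    if not include_his:
        basic_table.pop("HIS", None)

    def res_key(a: AtomRecord) -> str:
        return f"{a.res_name} {a.res_seq} {a.chain_id}"

    chain_bounds: dict[str, tuple[int, int]] = {}
    for a in model.atoms:
        lo, hi = chain_bounds.get(a.chain_id, (a.res_seq, a.res_seq))
        chain_bounds[a.chain_id] = (min(lo, a.res_seq), max(hi, a.res_seq))

    basic, acidic = [], []
    for a in model.atoms:
        lo, hi = chain_bounds[a.chain_id]
        if a.name in basic_table.get(a.res_name, ()):
            basic.append(a)
        elif include_termini and a.name == "N" and a.res_seq == lo:
            basic.append(a)  # free alpha-amino terminus
        if a.name in ACIDIC_ATOMS.get(a.res_name, ()):
            acidic.append(a)
        elif include_termini and a.name == "OXT" and a.res_seq == hi:
            acidic.append(a)  # carboxy terminus

    best: dict[tuple[str, str], float] = {}
    for b in basic:
        for c in acidic:
            if res_key(b) == res_key(c):
                continue
            d = float(np.linalg.norm(np.subtract(b.xyz, c.xyz)))
            if d <= cutoff:
                key = (res_key(b), res_key(c))
                if d < best.get(key, np.inf):
                    best[key] = d
    return [
        SaltBridge(basic_residue=k[0], acidic_residue=k[1], distance=v)
        for k, v in sorted(best.items(), key=lambda kv: kv[1])
    ]
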