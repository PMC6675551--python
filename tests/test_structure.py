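"""PDB parsing, superposition RMSD, SASA and salt-bridge detection."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from neopept.structure import (
    ELEMENT_RADII,
    AtomRecord,
    PdbFormatError,
    PmhcModel,
    detect_salt_bridges,
    hydrophobic_exposed_area,
    peptide_rmsd,
    read_pdb,
    relative_area_change,
    sasa,
    write_pdb,
)
from neopept.synthetic import SimConfig, gen_toy_pmhc


def _atom(name, element, res_name, res_seq, chain, xyz):
    return AtomRecord(
        name=name,
        element=element,
        res_name=res_name,
        res_seq=res_seq,
        chain_id=chain,
        xyz=tuple(float(v) for v in xyz),
        radius=ELEMENT_RADII[element],
    )


def _pdb_line(serial, name, res, chain, res_seq, x, y, z, element):
    pname = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {pname} {res:>3s} {chain}{res_seq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
        f"{element:>2s}\n"
    )


class TestReadPdb:
    def test_two_atom_toy_file(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(
            _pdb_line(1, "CA", "ALA", "C", 1, 1.0, 2.0, 3.0, "C")
            + _pdb_line(2, "N", "ALA", "C", 1, 4.0, 5.0, 6.0, "N")
        )
        model = read_pdb(path)
        assert len(model.atoms) == 2
        assert model.atoms[0].xyz == (1.0, 2.0, 3.0)
        assert model.atoms[1].element == "N"

    def test_only_first_model_read(self, tmp_path):
        path = tmp_path / "two_models.pdb"
        path.write_text(
            "MODEL        1\n"
            + _pdb_line(1, "CA", "ALA", "C", 1, 0, 0, 0, "C")
            + "ENDMDL\n"
            + "MODEL        2\n"
            + _pdb_line(1, "CA", "ALA", "C", 1, 9, 9, 9, "C")
            + "ENDMDL\n"
        )
        model = read_pdb(path)
        assert len(model.atoms) == 1
        assert model.atoms[0].xyz == (0.0, 0.0, 0.0)

    def test_malformed_record_names_the_line(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            _pdb_line(1, "CA", "ALA", "C", 1, 0, 0, 0, "C")
            + "ATOM  garbage line that cannot be parsed\n"
        )
        with pytest.raises(PdbFormatError, match="line 2"):
            read_pdb(path)

    def test_waters_and_hetatm_dropped(self, tmp_path):
        path = tmp_path / "het.pdb"
        path.write_text(
            _pdb_line(1, "CA", "ALA", "C", 1, 0, 0, 0, "C")
            + _pdb_line(2, "O", "HOH", "W", 1, 5, 5, 5, "O").replace(
                "ATOM  ", "HETATM"
            )
        )
        model = read_pdb(path)
        assert len(model.atoms) == 1

    def test_write_read_round_trip(self, tmp_path):
        ref, _ = gen_toy_pmhc("TGAARFDEF", SimConfig(seed=3))
        path = tmp_path / "model.pdb"
        write_pdb(ref, path)
        back = read_pdb(path, peptide_chain="C", mhc_chain="A")
        assert len(back.atoms) == len(ref.atoms)
        np.testing.assert_allclose(
            back.coords(), ref.coords(), atol=1e-3
        )


class TestPeptideRmsd:
    def test_model_vs_itself_is_zero(self):
        ref, _ = gen_toy_pmhc("TGAARFDEF", SimConfig(seed=3))
        for selection in ("backbone", "common_heavy"):
            assert peptide_rmsd(ref, ref, selection).rmsd == pytest.approx(
                0.0, abs=1e-7
            )

    def test_rigid_motion_removed_by_superposition(self):
        ref, _ = gen_toy_pmhc("TGAARFDEF", SimConfig(seed=3))
        rot = Rotation.from_euler("xyz", [10, 20, 30], degrees=True)
        shift = np.array([5.0, -3.0, 7.0])
        moved = PmhcModel(
            atoms=tuple(
                replace(
                    a,
                    xyz=tuple(float(v) for v in rot.apply(a.xyz) + shift),
                )
                for a in ref.atoms
            ),
            peptide_chain="C",
            mhc_chain="A",
        )
        report = peptide_rmsd(ref, moved, "common_heavy")
        assert report.rmsd == pytest.approx(0.0, abs=1e-6)

    def test_single_atom_displacement_closed_form(self):
        ref, _ = gen_toy_pmhc("TGAARFDEF", SimConfig(seed=3))
        d = 2.5
        pep_idx = [
            i for i, a in enumerate(ref.atoms)
            if a.chain_id == "C" and a.name in ("N", "CA", "C", "O")
        ]
        atoms = list(ref.atoms)
        target = pep_idx[4]
        a = atoms[target]
        atoms[target] = replace(a, xyz=(a.xyz[0], a.xyz[1], a.xyz[2] + d))
        moved = PmhcModel(atoms=tuple(atoms), peptide_chain="C", mhc_chain="A")
        report = peptide_rmsd(ref, moved, "backbone")
        assert report.rmsd == pytest.approx(
            d / math.sqrt(report.n_atoms), rel=1e-6
        )

    def test_symmetric_in_arguments(self):
        ref, per = gen_toy_pmhc("TGAARFDEF", SimConfig(seed=3), 0.4)
        a = peptide_rmsd(ref, per, "backbone").rmsd
        b = peptide_rmsd(per, ref, "backbone").rmsd
        assert a == pytest.approx(b, rel=1e-9)

    def test_length_mismatch_rejected(self):
        a, _ = gen_toy_pmhc("TGAARFDEF", SimConfig(seed=3))
        b, _ = gen_toy_pmhc("TGAARFDEFL", SimConfig(seed=3))
        with pytest.raises(ValueError):
            peptide_rmsd(a, b, "backbone")


def _single_atom_model(element="C", chain="C"):
    return PmhcModel(
        atoms=(_atom("CA", element, "ALA", 1, chain, (0, 0, 0)),),
        peptide_chain=chain,
        mhc_chain="A",
    )


class TestSasa:
    def test_isolated_atom_matches_analytic_sphere(self):
        model = _single_atom_model()
        report = sasa(model, n_points=960)
        expected = 4 * math.pi * (1.70 + 1.4) ** 2
        assert report.per_atom[0] == pytest.approx(expected, rel=1e-6)

    def test_convergence_with_point_count(self):
        model = _single_atom_model()
        a = sasa(model, n_points=960).per_atom[0]
        b = sasa(model, n_points=1920).per_atom[0]
        assert abs(a - b) / b < 0.01

    def test_two_nearly_coincident_atoms_cover_one_sphere(self):
        model = PmhcModel(
            atoms=(
                _atom("C1", "C", "ALA", 1, "C", (0, 0, 0)),
                _atom("C2", "C", "ALA", 1, "C", (0.001, 0, 0)),
            ),
            peptide_chain="C",
            mhc_chain="A",
        )
        report = sasa(model)
        one_sphere = 4 * math.pi * 3.1**2
        total = report.per_atom[0] + report.per_atom[1]
        assert total == pytest.approx(one_sphere, rel=0.02)

    def test_distant_atoms_add(self):
        model = PmhcModel(
            atoms=(
                _atom("C1", "C", "ALA", 1, "C", (0, 0, 0)),
                _atom("C2", "C", "ALA", 2, "C", (50, 0, 0)),
            ),
            peptide_chain="C",
            mhc_chain="A",
        )
        report = sasa(model)
        one_sphere = 4 * math.pi * 3.1**2
        assert report.per_atom[0] + report.per_atom[1] == pytest.approx(
            2 * one_sphere, rel=1e-6
        )

    def test_hydrophobic_never_exceeds_total(self):
        ref, _ = gen_toy_pmhc("TGAARFDEF", SimConfig(seed=3))
        report = sasa(ref)
        assert 0 <= report.peptide_hydrophobic <= report.peptide_total


class TestHydrophobicArea:
    def test_relative_change_formula(self):
        # the WT/mutant exposed-area pair 111 -> 139 A^2 corresponds to a
        # 25% relative increase
        assert relative_area_change(111.0, 139.0) == pytest.approx(
            0.25, abs=0.005
        )

    def test_isolated_carbon_chain_is_all_hydrophobic(self):
        # two bonded carbons far from anything polar: hydrophobic area
        # equals total carbon SASA
        model = PmhcModel(
            atoms=(
                _atom("C1", "C", "ALA", 1, "C", (0, 0, 0)),
                _atom("C2", "C", "ALA", 1, "C", (1.5, 0, 0)),
            ),
            peptide_chain="C",
            mhc_chain="A",
        )
        report = sasa(model)
        hydro = hydrophobic_exposed_area(model)
        assert hydro == pytest.approx(report.peptide_total, rel=1e-9)

    def test_carbon_bonded_to_oxygen_not_hydrophobic(self):
        model = PmhcModel(
            atoms=(
                _atom("C", "C", "ALA", 1, "C", (0, 0, 0)),
                _atom("O", "O", "ALA", 1, "C", (1.2, 0, 0)),
            ),
            peptide_chain="C",
            mhc_chain="A",
        )
        assert hydrophobic_exposed_area(model) == 0.0

    def test_zero_wt_area_rejected(self):
        with pytest.raises(ValueError):
            relative_area_change(0.0, 10.0)


class TestSaltBridges:
    def _arg_asp_model(self, distance):
        return PmhcModel(
            atoms=(
                _atom("NH1", "N", "ARG", 5, "C", (0, 0, 0)),
                _atom("NH2", "N", "ARG", 5, "C", (0.0, 2.0, 0)),
                _atom("OD1", "O", "ASP", 77, "A", (distance, 0, 0)),
                _atom("OD2", "O", "ASP", 77, "A", (distance + 0.5, 0.5, 0)),
            ),
            peptide_chain="C",
            mhc_chain="A",
        )

    def test_contact_under_cutoff_reported(self):
        bridges = detect_salt_bridges(self._arg_asp_model(3.5))
        assert len(bridges) == 1
        assert bridges[0].basic_residue == "ARG 5 C"
        assert bridges[0].acidic_residue == "ASP 77 A"
        assert bridges[0].distance == pytest.approx(3.5)

    def test_contact_beyond_cutoff_ignored(self):
        assert detect_salt_bridges(self._arg_asp_model(5.0)) == []

    def test_multiple_atom_pairs_collapse_to_minimum(self):
        # both NH1 and NH2 sit within the cutoff of the same Asp; one
        # record at the minimum distance is reported
        model = self._arg_asp_model(2.8)
        bridges = detect_salt_bridges(model)
        assert len(bridges) == 1
        assert bridges[0].distance == pytest.approx(2.8)

    def test_invariant_under_rigid_motion(self):
        model = self._arg_asp_model(3.5)
        rot = Rotation.from_euler("zyx", [15, 25, 35], degrees=True)
        moved = PmhcModel(
            atoms=tuple(
                replace(
                    a,
                    xyz=tuple(
                        float(v) for v in rot.apply(a.xyz) + [1.0, 2.0, 3.0]
                    ),
                )
                for a in model.atoms
            ),
            peptide_chain="C",
            mhc_chain="A",
        )
        orig = detect_salt_bridges(model)
        after = detect_salt_bridges(moved)
        assert [(b.basic_residue, b.acidic_residue) for b in orig] == [
            (b.basic_residue, b.acidic_residue) for b in after
        ]
        assert after[0].distance == pytest.approx(orig[0].distance, abs=1e-9)
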