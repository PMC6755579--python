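"""PDBQT parsing, torsion-tree geometry, conformation mapping and RMSD."""

import math

import numpy as np
import pytest

from chaosdock.ligand import (
    Conformation,
    apply_conformation,
    dihedral,
    is_success,
    quat_from_axis_angle,
    quat_multiply,
    quat_to_matrix,
    random_unit_quat,
    rmsd,
    wrap_angle,
)
from chaosdock.pdbqt import (
    PDBQTError,
    parse_pdbqt_ligand,
    parse_pdbqt_receptor,
    write_pdbqt_ligand,
)


def _atom(serial, name, t, x, y, z, q=0.0):
    return (
        f"ATOM  {serial:5d} {name:<4s} LIG A   1    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00    {q:6.3f} {t:<2s}"
    )


RIGID = "\n".join(
    [
        "ROOT",
        _atom(1, "C1", "C", 0.0, 0.0, 0.0),
        _atom(2, "C2", "C", 1.5, 0.0, 0.0),
        _atom(3, "O1", "OA", -1.2, 0.8, 0.0, q=-0.4),
        "ENDROOT",
        "TORSDOF 0",
    ]
)

# butane-like chain with two nested rotatable bonds
FLEX = "\n".join(
    [
        "ROOT",
        _atom(1, "C1", "C", 0.0, 0.0, 0.0),
        _atom(2, "C2", "C", 1.5, 0.0, 0.0),
        "ENDROOT",
        "BRANCH 2 3",
        _atom(3, "C3", "C", 2.1, 1.4, 0.0),
        "BRANCH 3 4",
        _atom(4, "C4", "C", 3.6, 1.5, 0.0),
        _atom(5, "N1", "N", 4.2, 2.9, 0.2, q=-0.3),
        "ENDBRANCH 3 4",
        "ENDBRANCH 2 3",
        "TORSDOF 2",
    ]
)


class TestParsing:
    def test_rigid_ligand(self):
        lig = parse_pdbqt_ligand(RIGID)
        assert lig.n_torsions == 0
        assert lig.dimension == 7
        assert [a.ad4_type for a in lig.atoms] == ["C", "C", "OA"]
        assert lig.atoms[2].is_hbond_acceptor
        assert lig.atoms[0].is_hydrophobic
        assert lig.atoms[2].partial_charge == pytest.approx(-0.4)

    def test_nested_branches(self):
        lig = parse_pdbqt_ligand(FLEX)
        assert lig.n_torsions == 2
        outer, inner = lig.tree.branches
        assert set(inner.moved) < set(outer.moved)
        assert lig.tree.root_atoms == (0, 1)
        assert outer.parent == 1 and outer.child == 2

    def test_round_trip(self):
        lig = parse_pdbqt_ligand(FLEX)
        again = parse_pdbqt_ligand(write_pdbqt_ligand(lig))
        assert again.n_torsions == lig.n_torsions
        assert again.tree == lig.tree
        np.testing.assert_allclose(again.ref_coords, lig.ref_coords, atol=1e-3)
        assert [a.ad4_type for a in again.atoms] == [a.ad4_type for a in lig.atoms]

    def test_unbalanced_branch_error(self):
        bad = FLEX.replace("ENDBRANCH 2 3\n", "")
        with pytest.raises(PDBQTError, match="unbalanced|unclosed"):
            parse_pdbqt_ligand(bad)

    def test_unknown_ad4_type_error(self):
        bad = RIGID.replace(" C \n", " Xx\n").replace(
            _atom(1, "C1", "C", 0.0, 0.0, 0.0),
            _atom(1, "C1", "Xx", 0.0, 0.0, 0.0),
        )
        with pytest.raises(PDBQTError, match="Xx"):
            parse_pdbqt_ligand(bad)

    def test_receptor_parsing(self):
        atoms = parse_pdbqt_receptor(
            "\n".join(
                [
                    _atom(1, "C1", "C", 0, 0, 0),
                    "HETATM    2 O1   LIG A   1       1.000   0.000   0.000  1.00  0.00    -0.40 OA",
                    _atom(3, "N1", "N", 0, 1.0, 0),
                ]
            )
        )
        assert len(atoms) == 3

    def test_empty_receptor_error(self):
        with pytest.raises(PDBQTError, match="no atoms"):
            parse_pdbqt_receptor("REMARK nothing here\n")

    def test_donor_flag_from_polar_hydrogen(self):
        text = "\n".join(
            [
                "ROOT",
                _atom(1, "N1", "N", 0, 0, 0, q=-0.35),
                _atom(2, "H1", "HD", 1.0, 0, 0, q=0.17),
                _atom(3, "C1", "C", -1.5, 0, 0),
                "ENDROOT",
            ]
        )
        lig = parse_pdbqt_ligand(text)
        assert lig.atoms[0].is_hbond_donor
        assert not lig.atoms[2].is_hbond_donor


class TestConformation:
    def test_identity_reproduces_reference(self):
        lig = parse_pdbqt_ligand(FLEX)
        coords = apply_conformation(lig, lig.reference_conformation())
        assert rmsd(coords, lig.ref_coords) < 1e-12

    def test_translation_only(self):
        lig = parse_pdbqt_ligand(FLEX)
        conf = lig.reference_conformation()
        conf.position = conf.position + np.array([2.0, 0.0, 0.0])
        coords = apply_conformation(lig, conf)
        np.testing.assert_allclose(
            coords - lig.ref_coords, np.tile([2.0, 0.0, 0.0], (len(lig.atoms), 1)),
            atol=1e-12,
        )

    def test_torsion_changes_dihedral_by_its_angle(self):
        lig = parse_pdbqt_ligand(FLEX)
        conf = lig.reference_conformation()
        ref_dih = dihedral(*lig.ref_coords[[0, 1, 2, 3]])
        for angle in (np.pi, 1.0, -2.0):
            conf.torsions = np.array([angle, 0.0])
            coords = apply_conformation(lig, conf)
            new_dih = dihedral(*coords[[0, 1, 2, 3]])
            delta = wrap_angle(new_dih - ref_dih)
            assert delta == pytest.approx(wrap_angle(angle), abs=1e-9)
            # bond lengths are invariant
            for i, j in [(0, 1), (1, 2), (2, 3), (3, 4)]:
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(
                    np.linalg.norm(lig.ref_coords[i] - lig.ref_coords[j]), abs=1e-9
                )

    def test_rigid_body_distances_preserved(self, rng):
        lig = parse_pdbqt_ligand(FLEX)
        root = list(lig.tree.root_atoms)
        inner = list(lig.tree.branches[1].moved)
        for _ in range(20):
            conf = Conformation(
                position=rng.uniform(-5, 5, 3),
                orientation=random_unit_quat(rng),
                torsions=rng.uniform(-np.pi, np.pi, 2),
            )
            coords = apply_conformation(lig, conf)
            for group in (root, inner):
                for i in group:
                    for j in group:
                        assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(
                            np.linalg.norm(lig.ref_coords[i] - lig.ref_coords[j]),
                            abs=1e-9,
                        )

    def test_torsion_composition_is_additive(self):
        lig = parse_pdbqt_ligand(FLEX)
        conf = lig.reference_conformation()
        conf.torsions = np.array([0.7 + 0.9, 0.0])
        direct = apply_conformation(lig, conf)
        # applying 0.7 then re-rooting the result and applying 0.9 must agree
        conf.torsions = np.array([0.7, 0.0])
        mid = apply_conformation(lig, conf)
        lig2 = parse_pdbqt_ligand(write_pdbqt_ligand(lig, coords=mid))
        conf2 = lig2.reference_conformation()
        conf2.torsions = np.array([0.9, 0.0])
        stepwise = apply_conformation(lig2, conf2)
        assert rmsd(direct, stepwise) < 1e-2  # PDBQT coordinates carry 3 decimals

    def test_dimension_mismatch_rejected(self):
        lig = parse_pdbqt_ligand(RIGID)
        conf = Conformation(
            position=np.zeros(3),
            orientation=np.array([1.0, 0, 0, 0]),
            torsions=np.array([0.5]),
        )
        with pytest.raises(ValueError, match="dimension"):
            apply_conformation(lig, conf)

    def test_quaternion_is_normalized(self):
        conf = Conformation(
            position=np.zeros(3),
            orientation=np.array([2.0, 0.0, 0.0, 0.0]),
            torsions=np.zeros(0),
        )
        assert np.linalg.norm(conf.orientation) == pytest.approx(1.0, abs=1e-12)

    def test_quat_matrix_round_trip(self, rng):
        q = random_unit_quat(rng)
        R = quat_to_matrix(q)
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)
        q2 = quat_multiply(quat_from_axis_angle([0.3, -0.2, 0.9]), q)
        assert np.linalg.norm(q2) == pytest.approx(1.0, abs=1e-12)


class TestRmsd:
    def test_identical_and_shift(self):
        a = np.random.default_rng(0).normal(size=(5, 3))
        assert rmsd(a, a) == 0.0
        assert rmsd(a, a + [2.0, 0.0, 0.0]) == pytest.approx(2.0, rel=1e-12)

    def test_single_displaced_atom(self):
        a = np.zeros((4, 3))
        b = a.copy()
        b[0, 0] = 4.0
        assert rmsd(a, b) == pytest.approx(2.0, rel=1e-12)  # sqrt(16/4)

    def test_metric_properties(self, rng):
        for _ in range(25):
            a, b, c = rng.normal(size=(3, 6, 3))
            assert rmsd(a, b) == pytest.approx(rmsd(b, a), rel=1e-12)
            assert rmsd(a, a) == 0.0
            assert rmsd(a, c) <= rmsd(a, b) + rmsd(b, c) + 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))

    @pytest.mark.parametrize(
        "value, expected", [(2.0, True), (0.0, True), (2.0001, False), (1.99, True)]
    )
    def test_success_threshold_inclusive(self, value, expected):
        assert is_success(value) is expected

    def test_negative_rmsd_rejected(self):
        with pytest.raises(ValueError):
            is_success(-0.1)
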