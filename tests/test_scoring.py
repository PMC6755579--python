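"""Empirical scoring function: terms, pair sums, gradients, invariances."""

import math

import numpy as np
import pytest

from chaosdock.engine import DockingObjective
from chaosdock.ligand import (
    Conformation,
    apply_conformation,
    quat_multiply,
    quat_from_axis_angle,
    random_unit_quat,
)
from chaosdock.pdbqt import Atom, parse_pdbqt_ligand
from chaosdock.scoring import (
    EnergyBreakdown,
    InteractionModel,
    ScoringParams,
    gradient,
    pair_potential,
    score,
)
from chaosdock.synthetic import make_toy_complex

P = ScoringParams()


def _vina_reference(d, hydrophobic=False, hbond=False, p=P):
    """Independent one-line evaluation of the published functional forms."""
    e = p.gauss1 * math.exp(-((d / 0.5) ** 2))
    e += p.gauss2 * math.exp(-(((d - 3.0) / 2.0) ** 2))
    if d < 0:
        e += p.repulsion * d * d
    if hydrophobic:
        e += p.hydrophobic * min(1.0, max(0.0, (1.5 - d) / 1.0))
    if hbond:
        e += p.hbond * min(1.0, max(0.0, -d / 0.7))
    return e


class TestPairPotential:
    def test_zero_beyond_cutoff(self):
        assert pair_potential(20.0, "C", "C") == 0.0

    def test_carbon_carbon_contact_value(self):
        # hand evaluation at d = 0: gauss1 at its peak, gauss2 at exp(-(3/2)^2),
        # no repulsion, hydrophobic ramp at its plateau
        expected = (
            P.gauss1 + P.gauss2 * math.exp(-2.25) + P.hydrophobic
        )
        assert pair_potential(0.0, "C", "C") == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("d", [-1.2, -0.3, 0.0, 0.4, 1.0, 2.5, 3.9])
    def test_matches_reference_forms(self, d):
        assert pair_potential(d, "C", "C") == pytest.approx(
            _vina_reference(d, hydrophobic=True), rel=1e-12
        )
        assert pair_potential(d, "OA", "N", hbond_pair=True) == pytest.approx(
            _vina_reference(d, hbond=True), rel=1e-12
        )

    def test_repulsion_piecewise(self):
        p0 = pair_potential(0.5, "N", "N")
        assert _vina_reference(0.5) == pytest.approx(p0, rel=1e-12)  # no repulsion
        d = -0.8
        gauss_only = P.gauss1 * math.exp(-((d / 0.5) ** 2)) + P.gauss2 * math.exp(
            -(((d - 3.0) / 2.0) ** 2)
        )
        assert pair_potential(d, "N", "N") - gauss_only == pytest.approx(
            P.repulsion * d * d, rel=1e-12
        )

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError, match="unknown AD4"):
            pair_potential(0.0, "C", "Qq")


def _random_system(rng, n_rec=50, n_lig=6):
    types = ["C", "N", "OA", "A", "SA"]
    rec = [
        Atom(serial=i + 1, name="X", ad4_type=types[int(rng.integers(len(types)))],
             coords=rng.uniform(-8, 8, 3))
        for i in range(n_rec)
    ]
    lines = ["ROOT"]
    for i in range(n_lig):
        x, y, z = rng.uniform(-2, 2, 3)
        t = types[int(rng.integers(len(types)))]
        lines.append(
            f"ATOM  {i+1:5d} {'X':<4s} LIG A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00     0.000 {t:<2s}"
        )
    lines.append("ENDROOT")
    lig = parse_pdbqt_ligand("\n".join(lines))
    return rec, lig


class TestScore:
    def test_rigid_ligand_divisor_is_one(self, toy_rigid):
        bd = score(toy_rigid.receptor, toy_rigid.ligand,
                   toy_rigid.crystal_conformation)
        assert bd.torsion_penalty_divisor == 1.0
        assert bd.affinity == pytest.approx(bd.intermolecular, rel=1e-12)

    def test_flexible_ligand_divisor(self, toy_flex):
        bd = score(toy_flex.receptor, toy_flex.ligand,
                   toy_flex.crystal_conformation)
        assert bd.torsion_penalty_divisor == pytest.approx(
            1.0 + P.torsion_weight * 2, rel=1e-12
        )
        assert bd.affinity == pytest.approx(
            bd.intermolecular / bd.torsion_penalty_divisor, rel=1e-12
        )

    def test_distant_receptor_scores_zero(self):
        rec = [Atom(serial=1, name="C", ad4_type="C", coords=[20.0, 0, 0])]
        lig = parse_pdbqt_ligand(
            "ROOT\n"
            "ATOM      1 C1   LIG A   1       0.000   0.000   0.000  1.00  0.00     0.000 C \n"
            "ENDROOT\n"
        )
        bd = score(rec, lig, lig.reference_conformation())
        assert bd.intermolecular == 0.0

    @pytest.mark.parametrize("pair", [("auto", "brute"), ("tree", "brute")])
    def test_evaluation_paths_agree(self, rng, pair):
        """Neighbor-list / compiled paths equal the O(N^2) reference."""
        for _ in range(5):
            rec, lig = _random_system(rng)
            model = InteractionModel(rec, lig)
            coords = apply_conformation(lig, lig.reference_conformation())
            e1 = model.energy(coords, method=pair[0])
            e2 = model.energy(coords, method=pair[1])
            assert e1[0] == pytest.approx(e2[0], abs=1e-10)
            assert e1[1] == pytest.approx(e2[1], abs=1e-10)

    def test_intramolecular_excludes_bonded_neighbors(self, toy_flex):
        model = InteractionModel(toy_flex.receptor, toy_flex.ligand)
        lig = toy_flex.ligand
        heavy = list(lig.heavy_indices)
        for i, j in zip(model.intra_i, model.intra_j):
            gi, gj = heavy[i], heavy[j]
            d = np.linalg.norm(lig.ref_coords[gi] - lig.ref_coords[gj])
            assert d > 1.75  # never a directly bonded pair


class TestGradient:
    def test_isolated_rigid_ligand_zero_gradient(self):
        rec = [Atom(serial=1, name="C", ad4_type="C", coords=[50.0, 0, 0])]
        lig = parse_pdbqt_ligand(
            "ROOT\n"
            "ATOM      1 C1   LIG A   1       0.000   0.000   0.000  1.00  0.00     0.000 C \n"
            "ATOM      2 C2   LIG A   1       1.500   0.000   0.000  1.00  0.00     0.000 C \n"
            "ENDROOT\n"
        )
        g = gradient(rec, lig, lig.reference_conformation())
        assert np.allclose(g, 0.0)

    def test_analytic_matches_finite_difference(self, toy_flex, rng):
        """Central differences (h=1e-5) in the local chart."""
        obj = DockingObjective(toy_flex.receptor, toy_flex.ligand, toy_flex.box)
        x = toy_flex.crystal_conformation.to_vector()
        for _ in range(4):
            xp = obj.sanitize(x + 0.15 * rng.normal(size=x.size))
            s0, fun, grad, _ = obj.local_chart(xp)
            g = grad(s0)
            h = 1e-5
            fd = np.array(
                [(fun(s0 + h * e) - fun(s0 - h * e)) / (2 * h) for e in np.eye(s0.size)]
            )
            assert np.abs(g - fd).max() < 1e-4

    def test_translation_gradient_equals_pair_force_sum(self, toy_rigid):
        """Brute-force per-pair radial differentiation oracle."""
        rec, lig = toy_rigid.receptor, toy_rigid.ligand
        conf = toy_rigid.crystal_conformation
        g = gradient(rec, lig, conf)
        coords = apply_conformation(lig, conf)
        h = 1e-6
        expected = np.zeros(3)
        for k in range(3):
            for sign in (1, -1):
                shifted = Conformation(
                    position=conf.position + sign * h * np.eye(3)[k],
                    orientation=conf.orientation,
                    torsions=conf.torsions,
                )
                expected[k] += sign * score(rec, lig, shifted).total
        expected /= 2 * h
        assert np.abs(g[:3] - expected).max() < 1e-4

    def test_rigid_motion_invariance(self, toy_rigid, rng):
        """Jointly rotating receptor + pose leaves the affinity unchanged."""
        rec, lig = toy_rigid.receptor, toy_rigid.ligand
        conf = toy_rigid.crystal_conformation
        base = score(rec, lig, conf).affinity
        q = random_unit_quat(rng)
        from chaosdock.ligand import quat_to_matrix

        R = quat_to_matrix(q)
        t = rng.uniform(-3, 3, 3)
        rec_rot = [
            Atom(serial=a.serial, name=a.name, ad4_type=a.ad4_type,
                 coords=R @ a.coords + t, partial_charge=a.partial_charge)
            for a in rec
        ]
        for a, b in zip(rec, rec_rot):
            b.is_hbond_donor = a.is_hbond_donor
        conf_rot = Conformation(
            position=R @ conf.position + t,
            orientation=quat_multiply(q, conf.orientation),
            torsions=conf.torsions,
        )
        moved = score(rec_rot, lig, conf_rot).affinity
        assert moved == pytest.approx(base, abs=1e-8)

    def test_affinity_continuous_in_conformation(self, toy_rigid, rng):
        obj = DockingObjective(toy_rigid.receptor, toy_rigid.ligand, toy_rigid.box)
        x = toy_rigid.crystal_conformation.to_vector()
        f0 = obj.value(x)
        for eps in (1e-3, 1e-5, 1e-7):
            delta = rng.normal(size=x.size)
            delta /= np.linalg.norm(delta)
            f1 = obj.value(obj.sanitize(x + eps * delta))
            assert abs(f1 - f0) < 50 * eps + 1e-9


class TestParams:
    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            ScoringParams(cutoff=-1.0)

    def test_radius_override(self):
        p = ScoringParams(vdw_radii={"C": 2.5})
        assert p.radius("C") == 2.5
        assert p.radius("N") == 1.8

    def test_breakdown_total(self):
        bd = EnergyBreakdown(-3.0, 0.5, 1.25, -2.4)
        assert bd.total == pytest.approx((-3.0 + 0.5) / 1.25)
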