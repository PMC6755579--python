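"""Vina-style empirical scoring of a ligand pose against a rigid receptor.

The interaction energy is a weighted sum of five pairwise terms — two
attractive Gaussians, a quadratic steric repulsion, a hydrophobic contact
ramp and a hydrogen-bond ramp — each a function of the *surface* distance
d = r - R_i - R_j between heavy atoms, truncated at an interatomic cutoff.
The reported affinity divides the intermolecular part by a torsional
penalty 1 + w_rot * N_rot, rewarding rigid ligands. Charges present in
PDBQT files are not used: the default parameterization carries no
electrostatic term.

The module also provides the analytic gradient of the docking objective
with respect to the pose parameters (translation, orientation tangent,
torsions), which the BFGS local search consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from . import _kernels
from .ligand import LigandModel, Conformation, apply_conformation
from .pdbqt import AD4_TYPES, Atom

__all__ = [
    "ScoringParams",
    "EnergyBreakdown",
    "pair_potential",
    "score",
    "gradient",
    "InteractionModel",
]

#: maximum heavy-atom bond length (Angstrom) used to infer ligand topology
_BOND_CUTOFF = 1.75


@dataclass
class ScoringParams:
    """Term weights and geometry of the empirical scoring function.

    Defaults are the published AutoDock Vina weights; every field can be
    overridden from the YAML config.
    """

    gauss1: float = -0.035579
    gauss2: float = -0.005156
    repulsion: float = 0.840245
    hydrophobic: float = -0.035069
    hbond: float = -0.587439
    torsion_weight: float = 0.05846
    cutoff: float = 8.0  # Angstrom, on the interatomic distance r
    vdw_radii: dict = field(default_factory=dict)  # AD4 type -> radius override

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        for t, r in self.vdw_radii.items():
            if r <= 0:
                raise ValueError(f"vdW radius for {t!r} must be positive")

    def radius(self, ad4_type: str) -> float:
        if ad4_type in self.vdw_radii:
            return self.vdw_radii[ad4_type]
        try:
            return AD4_TYPES[ad4_type][0]
        except KeyError:
            raise ValueError(f"unknown AD4 atom type {ad4_type!r}") from None


@dataclass
class EnergyBreakdown:
    """Scored pose energies (kcal/mol)."""

    intermolecular: float
    intramolecular: float
    torsion_penalty_divisor: float
    affinity: float

    @property
    def total(self) -> float:
        """Search objective: (inter + intra) / divisor."""
        return (self.intermolecular + self.intramolecular) / self.torsion_penalty_divisor


def _terms(d, params: ScoringParams):
    """Weighted sum of the five distance terms at surface distance(s) d."""
    d = np.asarray(d, dtype=float)
    e = params.gauss1 * np.exp(-((d / 0.5) ** 2))
    e = e + params.gauss2 * np.exp(-(((d - 3.0) / 2.0) ** 2))
    e = e + params.repulsion * np.where(d < 0.0, d * d, 0.0)
    return e


def _ramp(d, lo, hi):
    """Linear ramp: 1 for d <= lo, 0 for d >= hi."""
    return np.clip((hi - d) / (hi - lo), 0.0, 1.0)


def _terms_grad(d, params: ScoringParams):
    """d/dd of the weighted gauss1+gauss2+repulsion sum."""
    d = np.asarray(d, dtype=float)
    g = params.gauss1 * np.exp(-((d / 0.5) ** 2)) * (-8.0 * d)
    g = g + params.gauss2 * np.exp(-(((d - 3.0) / 2.0) ** 2)) * (-0.5 * (d - 3.0))
    g = g + params.repulsion * np.where(d < 0.0, 2.0 * d, 0.0)
    return g


def _ramp_grad(d, lo, hi):
    inside = (d > lo) & (d < hi)
    return np.where(inside, -1.0 / (hi - lo), 0.0)


def pair_potential(d_surface: float, type_i: str, type_j: str,
                   params: ScoringParams | None = None,
                   hydrophobic_pair: bool | None = None,
                   hbond_pair: bool | None = None) -> float:
    """Interaction energy of one atom pair at surface distance ``d_surface``.

    The hydrophobic term applies when both atoms are hydrophobic types and
    the hydrogen-bond term when the pair can donate/accept; by default both
    are inferred from the AD4 types alone (type-level flags; donor status
    normally needs the molecular context, pass ``hbond_pair`` to override).
    Returns 0 beyond the interatomic cutoff.
    """
    params = params or ScoringParams()
    ri, rj = params.radius(type_i), params.radius(type_j)
    r = d_surface + ri + rj
    if r > params.cutoff:
        return 0.0
    if hydrophobic_pair is None:
        hydrophobic_pair = AD4_TYPES[type_i][1] and AD4_TYPES[type_j][1]
    if hbond_pair is None:
        hbond_pair = AD4_TYPES[type_i][2] or AD4_TYPES[type_j][2]
    e = float(_terms(d_surface, params))
    if hydrophobic_pair:
        e += params.hydrophobic * float(_ramp(d_surface, 0.5, 1.5))
    if hbond_pair:
        e += params.hbond * float(_ramp(d_surface, -0.7, 0.0))
    return e


def _atom_arrays(atoms: list[Atom], params: ScoringParams):
    heavy = [a for a in atoms if a.is_heavy]
    coords = np.array([a.coords for a in heavy])
    radii = np.array([params.radius(a.ad4_type) for a in heavy])
    phobic = np.array([a.is_hydrophobic for a in heavy])
    donor = np.array([a.is_hbond_donor for a in heavy])
    acceptor = np.array([a.is_hbond_acceptor for a in heavy])
    return heavy, coords, radii, phobic, donor, acceptor


class InteractionModel:
    """Precomputed pair data for repeated scoring of one receptor/ligand.

    The receptor is rigid, so its heavy atoms, a KD-tree over them, and all
    per-pair constants (radius sums, hydrophobic/h-bond pair masks, the
    intramolecular pair list) are computed once; ``energy`` and
    ``energy_grad`` then evaluate a pose's coordinates in vectorized form.
    """

    def __init__(self, receptor_atoms: list[Atom], ligand: LigandModel,
                 params: ScoringParams | None = None):
        self.params = params or ScoringParams()
        self.ligand = ligand
        p = self.params

        (self._rec_atoms, self.rec_coords, self.rec_radii, rec_phob,
         rec_don, rec_acc) = _atom_arrays(receptor_atoms, p)
        self.lig_idx = ligand.heavy_indices  # indices into the full atom list
        lig_atoms = [ligand.atoms[i] for i in self.lig_idx]
        self.lig_radii = np.array([p.radius(a.ad4_type) for a in lig_atoms])
        lig_phob = np.array([a.is_hydrophobic for a in lig_atoms])
        lig_don = np.array([a.is_hbond_donor for a in lig_atoms])
        lig_acc = np.array([a.is_hbond_acceptor for a in lig_atoms])

        # receptor-ligand pair constants, shape (M, N)
        self.radius_sum = self.rec_radii[:, None] + self.lig_radii[None, :]
        self.phobic_pair = rec_phob[:, None] & lig_phob[None, :]
        self.hbond_pair = (rec_don[:, None] & lig_acc[None, :]) | (
            rec_acc[:, None] & lig_don[None, :]
        )
        self.tree = cKDTree(self.rec_coords)

        self.divisor = 1.0 + p.torsion_weight * ligand.n_torsions
        self._build_intra(ligand, lig_phob, lig_don, lig_acc)

    # -- intramolecular pair list -------------------------------------
    def _build_intra(self, ligand, lig_phob, lig_don, lig_acc):
        n_all = len(ligand.atoms)
        ref = ligand.ref_coords
        # bond topology: distance-inferred heavy-atom bonds + branch bonds
        ii, jj = [], []
        heavy = set(int(i) for i in self.lig_idx)
        for i in range(n_all):
            for j in range(i + 1, n_all):
                if i in heavy and j in heavy and (
                    np.linalg.norm(ref[i] - ref[j]) < _BOND_CUTOFF
                ):
                    ii.append(i)
                    jj.append(j)
        for b in ligand.tree.branches:
            ii.append(b.parent)
            jj.append(b.child)
        graph = csr_matrix(
            (np.ones(2 * len(ii)), (ii + jj, jj + ii)), shape=(n_all, n_all)
        )
        nbonds = shortest_path(graph, method="D", unweighted=True)

        # rigid body of each atom: innermost branch containing it (-1 = root;
        # branches are stored outer-to-inner, so later assignments win)
        body = np.full(n_all, -1, dtype=int)
        for bi, b in enumerate(ligand.tree.branches):
            body[list(b.moved)] = bi

        pairs_i, pairs_j = [], []
        pos = {int(a): k for k, a in enumerate(self.lig_idx)}
        for i in heavy:
            for j in heavy:
                if j <= i:
                    continue
                if body[i] != body[j] and nbonds[i, j] > 3:
                    pairs_i.append(pos[i])
                    pairs_j.append(pos[j])
        self.intra_i = np.array(pairs_i, dtype=int)
        self.intra_j = np.array(pairs_j, dtype=int)
        if len(pairs_i):
            self.intra_radius_sum = self.lig_radii[self.intra_i] + self.lig_radii[self.intra_j]
            self.intra_phobic = lig_phob[self.intra_i] & lig_phob[self.intra_j]
            self.intra_hbond = (lig_don[self.intra_i] & lig_acc[self.intra_j]) | (
                lig_acc[self.intra_i] & lig_don[self.intra_j]
            )

    # -- evaluation ----------------------------------------------------
    def _pair_energy(self, d, phobic, hbond):
        p = self.params
        e = _terms(d, p)
        e += (p.hydrophobic * phobic) * _ramp(d, 0.5, 1.5)
        e += (p.hbond * hbond) * _ramp(d, -0.7, 0.0)
        return e

    def _pair_energy_grad(self, d, phobic, hbond):
        p = self.params
        g = _terms_grad(d, p)
        g += (p.hydrophobic * phobic) * _ramp_grad(d, 0.5, 1.5)
        g += (p.hbond * hbond) * _ramp_grad(d, -0.7, 0.0)
        return g

    def _inter_pairs(self, lig_coords, method):
        """Within-cutoff receptor-ligand pair indices and distances."""
        cutoff = self.params.cutoff
        if method != "tree":
            diff = self.rec_coords[:, None, :] - lig_coords[None, :, :]
            r = np.sqrt(np.sum(diff * diff, axis=2))
            mi, mj = np.nonzero(r <= cutoff)
            return mi, mj, r[mi, mj]
        pairs = self.tree.query_ball_point(lig_coords, cutoff)
        mi, mj = [], []
        for j, neigh in enumerate(pairs):
            mi.extend(neigh)
            mj.extend([j] * len(neigh))
        mi = np.array(mi, dtype=int)
        mj = np.array(mj, dtype=int)
        r = np.linalg.norm(self.rec_coords[mi] - lig_coords[mj], axis=1)
        return mi, mj, r

    def _dense_inter(self, lig):
        """Full-matrix intermolecular energy (fast path for small systems)."""
        p = self.params
        diff = lig[None, :, :] - self.rec_coords[:, None, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        d = r - self.radius_sum
        e = self._pair_energy(d, self.phobic_pair, self.hbond_pair)
        return float(np.sum(e[r <= p.cutoff]))

    def _dense_intra(self, lig):
        ri = np.linalg.norm(lig[self.intra_i] - lig[self.intra_j], axis=1)
        d = ri - self.intra_radius_sum
        e = self._pair_energy(d, self.intra_phobic, self.intra_hbond)
        return float(np.sum(e[ri <= self.params.cutoff]))

    def _weights(self):
        p = self.params
        return p.gauss1, p.gauss2, p.repulsion, p.hydrophobic, p.hbond

    def energy(self, coords, method: str = "auto") -> tuple[float, float]:
        """(intermolecular, intramolecular) energies at full-atom coords.

        ``method``: "auto" (compiled kernel when numba is available),
        "brute" (vectorized full-matrix reference) or "tree" (KD-tree
        neighbor list); all agree to ~1e-12.
        """
        lig = coords[self.lig_idx]
        if method == "auto" and _kernels.HAVE_NUMBA:
            inter = _kernels.energy_inter(
                self.rec_coords, lig, self.radius_sum, self.phobic_pair,
                self.hbond_pair, self.params.cutoff, *self._weights(),
            )
            intra = 0.0
            if len(self.intra_i):
                intra = _kernels.energy_intra(
                    lig, self.intra_i, self.intra_j, self.intra_radius_sum,
                    self.intra_phobic, self.intra_hbond, self.params.cutoff,
                    *self._weights(),
                )
            return inter, intra
        if method != "tree":
            inter = self._dense_inter(lig)
        else:
            mi, mj, r = self._inter_pairs(lig, method)
            inter = float(
                np.sum(
                    self._pair_energy(
                        r - self.radius_sum[mi, mj],
                        self.phobic_pair[mi, mj],
                        self.hbond_pair[mi, mj],
                    )
                )
            ) if len(mi) else 0.0
        intra = self._dense_intra(lig) if len(self.intra_i) else 0.0
        return inter, intra

    def energy_grad(self, coords, method: str = "auto"):
        """Energies plus d(inter+intra)/d(coords), full-atom shape (N, 3)."""
        lig = coords[self.lig_idx]
        grad_lig = np.zeros_like(lig)
        if method == "auto" and _kernels.HAVE_NUMBA:
            inter = _kernels.energy_grad_inter(
                self.rec_coords, lig, self.radius_sum, self.phobic_pair,
                self.hbond_pair, self.params.cutoff, *self._weights(), grad_lig,
            )
            intra = 0.0
            if len(self.intra_i):
                intra = _kernels.energy_grad_intra(
                    lig, self.intra_i, self.intra_j, self.intra_radius_sum,
                    self.intra_phobic, self.intra_hbond, self.params.cutoff,
                    *self._weights(), grad_lig,
                )
            grad = np.zeros_like(coords)
            grad[self.lig_idx] = grad_lig
            return inter, intra, grad
        mi, mj, r = self._inter_pairs(lig, "brute" if method != "tree" else "tree")
        inter = 0.0
        if len(mi):
            d = r - self.radius_sum[mi, mj]
            phob = self.phobic_pair[mi, mj]
            hb = self.hbond_pair[mi, mj]
            inter = float(np.sum(self._pair_energy(d, phob, hb)))
            dVdr = self._pair_energy_grad(d, phob, hb)
            rsafe = np.where(r < 1e-9, 1e-9, r)
            unit = (lig[mj] - self.rec_coords[mi]) / rsafe[:, None]
            np.add.at(grad_lig, mj, dVdr[:, None] * unit)
        intra = 0.0
        if len(self.intra_i):
            vec = lig[self.intra_i] - lig[self.intra_j]
            ri = np.linalg.norm(vec, axis=1)
            mask = ri <= self.params.cutoff
            if np.any(mask):
                d = ri[mask] - self.intra_radius_sum[mask]
                phob = self.intra_phobic[mask]
                hb = self.intra_hbond[mask]
                intra = float(np.sum(self._pair_energy(d, phob, hb)))
                dVdr = self._pair_energy_grad(d, phob, hb)
                rsafe = np.where(ri[mask] < 1e-9, 1e-9, ri[mask])
                unit = vec[mask] / rsafe[:, None]
                np.add.at(grad_lig, self.intra_i[mask], dVdr[:, None] * unit)
                np.add.at(grad_lig, self.intra_j[mask], -dVdr[:, None] * unit)
        grad = np.zeros_like(coords)
        grad[self.lig_idx] = grad_lig
        return inter, intra, grad

    def breakdown(self, inter: float, intra: float) -> EnergyBreakdown:
        return EnergyBreakdown(
            intermolecular=inter,
            intramolecular=intra,
            torsion_penalty_divisor=self.divisor,
            affinity=inter / self.divisor,
        )


def score(receptor_atoms, ligand: LigandModel, conf: Conformation,
          params: ScoringParams | None = None,
          method: str = "auto") -> EnergyBreakdown:
    """Score one conformation; ``method`` in {"auto", "brute", "tree"}."""
    model = InteractionModel(receptor_atoms, ligand, params)
    coords = apply_conformation(ligand, conf)
    inter, intra = model.energy(coords, method=method)
    return model.breakdown(inter, intra)


def conf_gradient(model: InteractionModel, position, coords: np.ndarray):
    """Objective value and gradient in pose-tangent space.

    ``position`` is the root-center placement of the pose whose full-atom
    ``coords`` are given. Returns ``(value, g)`` where value =
    (inter + intra)/divisor and g has 3 translation components, 3
    orientation-tangent components (axis-angle increment applied in the
    world frame about the current orientation) and one per torsion.
    """
    ligand = model.ligand
    inter, intra, dcoords = model.energy_grad(coords)
    dcoords = dcoords / model.divisor
    value = (inter + intra) / model.divisor

    if _kernels.HAVE_NUMBA:
        g = np.empty(6 + ligand.n_torsions)
        parents, childs, moved_flat, moved_off = ligand.packed_tree
        _kernels.pose_gradient(
            coords, dcoords, np.asarray(position, dtype=float),
            parents, childs, moved_flat, moved_off, g,
        )
        return value, g

    g = np.zeros(6 + ligand.n_torsions)
    g[0:3] = dcoords.sum(axis=0)
    rel = coords - np.asarray(position)
    g[3:6] = _cross_sum(rel, dcoords)
    for k, b in enumerate(ligand.tree.branches):
        axis = coords[b.child] - coords[b.parent]
        axis = axis / math.sqrt(float(axis @ axis))
        moved = list(b.moved)
        rel_b = coords[moved] - coords[b.child]
        g[6 + k] = float(_cross_sum(rel_b, dcoords[moved]) @ axis)
    return value, g


def _cross_sum(a, b):
    """sum_i a_i x b_i without np.cross overhead."""
    return np.array(
        [
            float(a[:, 1] @ b[:, 2]) - float(a[:, 2] @ b[:, 1]),
            float(a[:, 2] @ b[:, 0]) - float(a[:, 0] @ b[:, 2]),
            float(a[:, 0] @ b[:, 1]) - float(a[:, 1] @ b[:, 0]),
        ]
    )


def gradient(receptor_atoms, ligand: LigandModel, conf: Conformation,
             params: ScoringParams | None = None) -> np.ndarray:
    """Analytic gradient of the docking objective at a conformation.

    Components: d/d(position) (3), d/d(orientation tangent) (3, axis-angle
    about the current quaternion in the world frame), d/d(torsions) (n).
    """
    model = InteractionModel(receptor_atoms, ligand, params)
    coords = apply_conformation(ligand, conf)
    _, g = conf_gradient(model, conf.position, coords)
    return g
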