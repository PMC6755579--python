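"""Ligand conformational model: torsion tree, pose vector and RMSD.

A docked ligand pose is described by a :class:`Conformation` — a rigid-body
placement (translation + unit-quaternion orientation of the ROOT block)
plus one dihedral angle per rotatable bond. ``apply_conformation`` maps
that D = 7 + n_torsions vector onto Cartesian coordinates, starting from
the reference (file) coordinates: branch rotations are applied ancestors
first, each rotating its moved set about the parent->child bond axis by the
right-hand rule, then the whole ligand is rotated about its root center and
translated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels

__all__ = [
    "TorsionBranch",
    "TorsionTree",
    "LigandModel",
    "Conformation",
    "apply_conformation",
    "rmsd",
    "is_success",
    "SUCCESS_RMSD",
    "quat_to_matrix",
    "quat_multiply",
    "quat_from_axis_angle",
    "random_unit_quat",
    "wrap_angle",
    "dihedral",
]

#: pose-prediction success threshold: RMSD of 2 Angstrom or less
SUCCESS_RMSD = 2.0


@dataclass(frozen=True)
class TorsionBranch:
    """One rotatable bond: atom indices of the bond and its moved set."""

    parent: int
    child: int
    moved: tuple[int, ...]


@dataclass(frozen=True)
class TorsionTree:
    root_atoms: tuple[int, ...]
    branches: tuple[TorsionBranch, ...]


@dataclass
class LigandModel:
    """Atoms at reference (crystal/file) coordinates plus the torsion tree."""

    atoms: list
    tree: TorsionTree
    layout: tuple = ()

    def __post_init__(self):
        if self.n_heavy < 1:
            raise ValueError("ligand must contain at least one heavy atom")
        if not self.layout:
            self.layout = _default_layout(self.tree, len(self.atoms))

    @property
    def n_torsions(self) -> int:
        return len(self.tree.branches)

    @property
    def dimension(self) -> int:
        """Search-space dimension: 3 position + 4 quaternion + torsions."""
        return 7 + self.n_torsions

    @property
    def ref_coords(self) -> np.ndarray:
        # cached: reference coordinates are immutable for a given model
        cached = self.__dict__.get("_ref_coords")
        if cached is None:
            cached = np.array([a.coords for a in self.atoms])
            cached.setflags(write=False)
            self.__dict__["_ref_coords"] = cached
        return cached

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.is_heavy], dtype=int)

    @property
    def n_heavy(self) -> int:
        return sum(1 for a in self.atoms if a.is_heavy)

    @property
    def root_center(self) -> np.ndarray:
        """Geometric center of the ROOT atoms (reference frame)."""
        cached = self.__dict__.get("_root_center")
        if cached is None:
            cached = self.ref_coords[list(self.tree.root_atoms)].mean(axis=0)
            cached.setflags(write=False)
            self.__dict__["_root_center"] = cached
        return cached

    @property
    def packed_tree(self):
        """Torsion tree flattened to int arrays (parents, childs,
        moved_flat, moved_offsets) for the compiled kernels."""
        cached = self.__dict__.get("_packed_tree")
        if cached is None:
            branches = self.tree.branches
            parents = np.array([b.parent for b in branches], dtype=np.int64)
            childs = np.array([b.child for b in branches], dtype=np.int64)
            moved_flat = np.array(
                [i for b in branches for i in b.moved], dtype=np.int64
            )
            moved_off = np.zeros(len(branches) + 1, dtype=np.int64)
            for k, b in enumerate(branches):
                moved_off[k + 1] = moved_off[k] + len(b.moved)
            cached = (parents, childs, moved_flat, moved_off)
            self.__dict__["_packed_tree"] = cached
        return cached

    def reference_conformation(self) -> "Conformation":
        """The conformation that reproduces the file coordinates exactly."""
        return Conformation(
            position=self.root_center,
            orientation=np.array([1.0, 0.0, 0.0, 0.0]),
            torsions=np.zeros(self.n_torsions),
        )


def _default_layout(tree: TorsionTree, n_atoms: int) -> tuple:
    """Flat serialization layout for models built in code (root block, then
    each branch's own atoms in order, nesting sequentially)."""
    layout = [("ROOT",)] + [("ATOM", i) for i in tree.root_atoms] + [("ENDROOT",)]
    claimed = set(tree.root_atoms)
    for bi, b in enumerate(tree.branches):
        own = [i for i in b.moved if i not in claimed]
        claimed.update(own)
        layout.append(("BRANCH", bi))
        layout.extend(("ATOM", i) for i in own)
        layout.append(("ENDBRANCH", bi))
    return tuple(layout)


@dataclass
class Conformation:
    """Point in the ligand's search space.

    position : (3,) Angstrom, target location of the root center
    orientation : (4,) unit quaternion (w, x, y, z)
    torsions : (n,) dihedral offsets in radians, wrapped to (-pi, pi]
    """

    position: np.ndarray
    orientation: np.ndarray
    torsions: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        self.torsions = np.asarray(self.torsions, dtype=float)
        n = np.linalg.norm(self.orientation)
        if not math.isclose(n, 1.0, abs_tol=1e-9):
            if n <= 0 or not np.isfinite(n):
                raise ValueError("orientation quaternion has zero/invalid norm")
            self.orientation = self.orientation / n
        self.torsions = wrap_angle(self.torsions)

    @property
    def dimension(self) -> int:
        return 7 + self.torsions.size

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.position, self.orientation, self.torsions])

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "Conformation":
        x = np.asarray(x, dtype=float)
        return cls(position=x[:3], orientation=x[3:7], torsions=x[7:])


def wrap_angle(theta):
    """Wrap angles to the interval (-pi, pi]."""
    wrapped = -((-np.asarray(theta) + np.pi) % (2.0 * np.pi) - np.pi)
    return wrapped


def quat_multiply(q1, q2):
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def quat_from_axis_angle(axis_angle):
    """Quaternion of a rotation vector (axis scaled by angle in radians)."""
    v = np.asarray(axis_angle, dtype=float)
    theta = np.linalg.norm(v)
    if theta < 1e-12:
        return np.array([1.0, 0.5 * v[0], 0.5 * v[1], 0.5 * v[2]]) / math.sqrt(
            1.0 + 0.25 * (v @ v)
        )
    axis = v / theta
    s = math.sin(0.5 * theta)
    return np.array([math.cos(0.5 * theta), s * axis[0], s * axis[1], s * axis[2]])


def quat_to_matrix(q):
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def random_unit_quat(rng) -> np.ndarray:
    """Uniform random rotation (Gaussian 4-vector, normalized)."""
    q = rng.normal(size=4)
    n = np.linalg.norm(q)
    while n < 1e-12:  # pragma: no cover - probability zero
        q = rng.normal(size=4)
        n = np.linalg.norm(q)
    return q / n


def _axis_angle_matrix(axis, angle):
    n = math.sqrt(axis[0] * axis[0] + axis[1] * axis[1] + axis[2] * axis[2])
    ux, uy, uz = axis[0] / n, axis[1] / n, axis[2] / n
    c, s = math.cos(angle), math.sin(angle)
    t = 1.0 - c
    return np.array(
        [
            [c + t * ux * ux, t * ux * uy - s * uz, t * ux * uz + s * uy],
            [t * ux * uy + s * uz, c + t * uy * uy, t * uy * uz - s * ux],
            [t * ux * uz - s * uy, t * uy * uz + s * ux, c + t * uz * uz],
        ]
    )


def pose_coordinates(ligand: LigandModel, position, orientation,
                     torsions) -> np.ndarray:
    """Raw pose -> coordinates mapping (orientation must be unit norm)."""
    if _kernels.HAVE_NUMBA:
        out = np.empty_like(ligand.ref_coords)
        parents, childs, moved_flat, moved_off = ligand.packed_tree
        _kernels.pose_coords(
            ligand.ref_coords, parents, childs, moved_flat, moved_off,
            np.asarray(torsions, dtype=float), quat_to_matrix(orientation),
            ligand.root_center, np.asarray(position, dtype=float), out,
        )
        return out
    coords = ligand.ref_coords.copy()
    # torsions, ancestors first (branches are stored in file/opening order)
    for b, angle in zip(ligand.tree.branches, torsions):
        if angle == 0.0:
            continue
        pivot = coords[b.child]
        axis = pivot - coords[b.parent]
        R = _axis_angle_matrix(axis, angle)
        moved = list(b.moved)
        coords[moved] = (coords[moved] - pivot) @ R.T + pivot
    # rigid placement about the (torsion-invariant) root center
    R = quat_to_matrix(orientation)
    return (coords - ligand.root_center) @ R.T + position


def apply_conformation(ligand: LigandModel, conf: Conformation) -> np.ndarray:
    """Cartesian coordinates (N x 3) of the ligand at a conformation."""
    if conf.dimension != ligand.dimension:
        raise ValueError(
            f"conformation dimension {conf.dimension} != ligand dimension "
            f"{ligand.dimension}"
        )
    return pose_coordinates(ligand, conf.position, conf.orientation, conf.torsions)


def rmsd(coords_a, coords_b) -> float:
    """Root-mean-square deviation between two matched coordinate sets.

    No superposition is performed: poses are compared in the receptor
    frame, atom i against atom i. Pass heavy-atom coordinates only when
    scoring pose-prediction success.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def is_success(rmsd_value: float) -> bool:
    """Pose-prediction success: RMSD of 2 Angstrom or less (inclusive)."""
    if rmsd_value < 0:
        raise ValueError("RMSD cannot be negative")
    return rmsd_value <= SUCCESS_RMSD


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (radians) of four points about the p1-p2 axis."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    return math.atan2(np.cross(b1n, v) @ w, v @ w)
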