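"""End-to-end docking: search box, docking objective, repeated runs, ranking.

A docking job searches the D = 7 + n_torsions conformational space of a
flexible ligand inside an axis-aligned box over a rigid receptor. Each of
``n_runs`` repetitions is an independent chaos-embedded PSO search with its
own sub-seed; the resulting poses are de-duplicated by heavy-atom RMSD and
ranked by predicted affinity, the pose with the lowest affinity being the
final docking solution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ligand import (
    Conformation,
    LigandModel,
    apply_conformation,
    pose_coordinates,
    quat_from_axis_angle,
    quat_multiply,
    random_unit_quat,
    rmsd,
    wrap_angle,
)
from .optimizer import BoxObjective, SwarmConfig, pso_search
from .scoring import InteractionModel, ScoringParams, conf_gradient

__all__ = [
    "SearchBox",
    "PoseResult",
    "DockingObjective",
    "box_from_pocket",
    "box_from_ligand",
    "dock",
]

logger = logging.getLogger(__name__)

#: poses closer than this heavy-atom RMSD (Angstrom) are considered duplicates
DEDUP_RMSD = 1.0
#: maximum number of reported binding modes
MAX_MODES = 9
#: minimum box edge (Angstrom) after padding degenerate pockets
MIN_EDGE = 1.0
#: default box edge for ligand-centered boxes (Angstrom)
DEFAULT_EDGE = 22.5


@dataclass
class SearchBox:
    """Axis-aligned docking box: center and per-axis lengths (Angstrom)."""

    center: np.ndarray
    lengths: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.lengths = np.asarray(self.lengths, dtype=float).reshape(3)
        if np.any(self.lengths <= 0):
            raise ValueError(f"box lengths must be positive, got {self.lengths}")

    @property
    def lower(self) -> np.ndarray:
        return self.center - 0.5 * self.lengths

    @property
    def upper(self) -> np.ndarray:
        return self.center + 0.5 * self.lengths

    def contains(self, point) -> bool:
        p = np.asarray(point)
        return bool(np.all(p >= self.lower - 1e-9) and np.all(p <= self.upper + 1e-9))


def _coords_of(atoms) -> np.ndarray:
    if hasattr(atoms, "ndim"):
        return np.asarray(atoms, dtype=float)
    return np.array([a.coords for a in atoms], dtype=float)


def box_from_pocket(pocket_atoms) -> SearchBox:
    """Box spanned by the binding-pocket atoms.

    Center = geometric center of the pocket atoms; lengths = the largest
    pocket-atom extent along each axis. Degenerate (flat) pockets are
    padded to a minimum edge with a warning.
    """
    coords = _coords_of(pocket_atoms)
    if coords.shape[0] < 2:
        raise ValueError("pocket box needs at least 2 atoms")
    center = coords.mean(axis=0)
    lengths = coords.max(axis=0) - coords.min(axis=0)
    if np.any(lengths < MIN_EDGE):
        logger.warning(
            "degenerate pocket box lengths %s padded to %.1f A", lengths, MIN_EDGE
        )
        lengths = np.maximum(lengths, MIN_EDGE)
    return SearchBox(center=center, lengths=lengths)


def box_from_ligand(crystal_ligand, edge: float = DEFAULT_EDGE) -> SearchBox:
    """Cubic box of the given edge centered on the bound ligand."""
    if isinstance(crystal_ligand, LigandModel):
        coords = crystal_ligand.ref_coords
    else:
        coords = _coords_of(crystal_ligand)
    if coords.shape[0] < 1:
        raise ValueError("ligand is empty")
    return SearchBox(center=coords.mean(axis=0), lengths=np.full(3, float(edge)))


@dataclass
class PoseResult:
    """One scored docking pose."""

    conformation: Conformation
    coordinates: np.ndarray
    affinity: float  # kcal/mol
    run_index: int
    generations_used: int
    intermolecular: float = 0.0
    intramolecular: float = 0.0


class DockingObjective(BoxObjective):
    """Scoring-function objective over the pose vector.

    The PSO vector is [position (3), quaternion (4), torsions (n)];
    sanitization clamps the position into the box, renormalizes the
    quaternion and wraps torsions to (-pi, pi]. The BFGS local chart is
    the 6+n tangent space (translation, world-frame axis-angle increment
    about the current orientation, torsions), with the exact SO(3)
    left-Jacobian transform applied to the orientation gradient.
    """

    def __init__(self, receptor_atoms, ligand: LigandModel, box: SearchBox,
                 scoring: ScoringParams | None = None):
        self.box = box
        self.ligand = ligand
        self.model = InteractionModel(receptor_atoms, ligand, scoring)
        n = ligand.n_torsions
        lower = np.concatenate([box.lower, -np.ones(4), -np.pi * np.ones(n)])
        upper = np.concatenate([box.upper, np.ones(4), np.pi * np.ones(n)])
        super().__init__(7 + n, lower, upper)

    # -- vector plumbing ------------------------------------------------
    def sanitize(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float).copy()
        x[:3] = np.clip(x[:3], self.box.lower, self.box.upper)
        norm = np.linalg.norm(x[3:7])
        x[3:7] = np.array([1.0, 0.0, 0.0, 0.0]) if norm < 1e-12 else x[3:7] / norm
        x[7:] = wrap_angle(x[7:])
        return x

    def random_point(self, rng) -> np.ndarray:
        pos = rng.uniform(self.box.lower, self.box.upper)
        quat = random_unit_quat(rng)
        tors = rng.uniform(-np.pi, np.pi, size=self.ligand.n_torsions)
        return np.concatenate([pos, quat, tors])

    def vmax(self) -> np.ndarray:
        return np.concatenate(
            [0.5 * self.box.lengths, np.ones(4), np.pi * np.ones(self.ligand.n_torsions)]
        )

    # -- evaluation -----------------------------------------------------
    def _energy_at(self, x) -> tuple[float, np.ndarray]:
        q = x[3:7]
        q = q / np.linalg.norm(q)
        coords = pose_coordinates(self.ligand, x[:3], q, x[7:])
        inter, intra = self.model.energy(coords)
        return (inter + intra) / self.model.divisor, coords

    def value(self, x) -> float:
        return self._energy_at(np.asarray(x, dtype=float))[0]

    def breakdown(self, x):
        conf = Conformation.from_vector(x)
        coords = apply_conformation(self.ligand, conf)
        inter, intra = self.model.energy(coords)
        return conf, coords, self.model.breakdown(inter, intra)

    def local_chart(self, x):
        x = np.asarray(x, dtype=float)
        q_base = x[3:7] / np.linalg.norm(x[3:7])
        s0 = np.concatenate([x[:3], np.zeros(3), x[7:]])
        # the line search evaluates `fun` and then `grad` at the accepted
        # point; cache the pose coordinates to avoid recomputing them
        cache = {"s": None, "coords": None}

        def pose(s):
            q = quat_multiply(quat_from_axis_angle(s[3:6]), q_base)
            coords = pose_coordinates(self.ligand, s[:3], q, s[6:])
            cache["s"] = s.copy()
            cache["coords"] = coords
            return coords

        def fun(s):
            coords = pose(s)
            inter, intra = self.model.energy(coords)
            return (inter + intra) / self.model.divisor

        def grad(s):
            if cache["s"] is not None and np.array_equal(cache["s"], s):
                coords = cache["coords"]
            else:
                coords = pose(s)
            _, g = conf_gradient(self.model, s[:3], coords)
            g[3:6] = _so3_left_jacobian(s[3:6]).T @ g[3:6]
            return g

        def to_x(s):
            q = quat_multiply(quat_from_axis_angle(s[3:6]), q_base)
            return np.concatenate([s[:3], q, s[6:]])

        return s0, fun, grad, to_x


def _so3_left_jacobian(omega) -> np.ndarray:
    """Left Jacobian of SO(3) at rotation vector omega (chain rule between
    the axis-angle chart and the world-frame tangent)."""
    theta = float(np.linalg.norm(omega))
    W = np.array(
        [
            [0.0, -omega[2], omega[1]],
            [omega[2], 0.0, -omega[0]],
            [-omega[1], omega[0], 0.0],
        ]
    )
    if theta < 1e-8:
        return np.eye(3) + 0.5 * W + W @ W / 6.0
    return (
        np.eye(3)
        + (1.0 - np.cos(theta)) / theta**2 * W
        + (theta - np.sin(theta)) / theta**3 * (W @ W)
    )


def dock(receptor_atoms, ligand: LigandModel, box: SearchBox,
         cfg: SwarmConfig | None = None, n_runs: int = 10,
         scoring: ScoringParams | None = None) -> list[PoseResult]:
    """Dock one ligand: ``n_runs`` independent searches, ranked poses.

    Each run is a full PSO search with a distinct sub-seed derived from
    ``cfg.seed``. Poses within ``DEDUP_RMSD`` heavy-atom RMSD of a better
    pose are dropped; at most ``MAX_MODES`` poses are returned, sorted by
    ascending affinity.
    """
    cfg = cfg or SwarmConfig()
    extent = ligand.ref_coords.max(axis=0) - ligand.ref_coords.min(axis=0)
    if np.any(extent > box.lengths):
        logger.warning(
            "crystal ligand extent %s exceeds box lengths %s", extent, box.lengths
        )
    objective = DockingObjective(receptor_atoms, ligand, box, scoring)
    heavy = ligand.heavy_indices

    run_seeds = np.random.SeedSequence(cfg.seed).spawn(n_runs)
    poses: list[PoseResult] = []
    for run_index, sub in enumerate(run_seeds):
        gbest_x, gbest_f, generations = pso_search(objective, cfg, seed=sub)
        if not np.isfinite(gbest_f):
            continue
        conf, coords, bd = objective.breakdown(gbest_x)
        poses.append(
            PoseResult(
                conformation=conf,
                coordinates=coords,
                affinity=bd.affinity,
                run_index=run_index,
                generations_used=generations,
                intermolecular=bd.intermolecular,
                intramolecular=bd.intramolecular,
            )
        )
    if not poses:
        raise RuntimeError("all docking runs failed to produce a finite score")

    poses.sort(key=lambda p: p.affinity)
    kept: list[PoseResult] = []
    for pose in poses:
        if all(
            rmsd(pose.coordinates[heavy], k.coordinates[heavy]) >= DEDUP_RMSD
            for k in kept
        ):
            kept.append(pose)
        if len(kept) >= MAX_MODES:
            break
    return kept
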