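"""Synthetic fixtures: toy complexes with a planted pose, analytic objectives.

Nothing in the test stack depends on external structures: this module
generates miniature receptor/ligand PDBQT pairs whose global scoring
minimum is planted by construction, plus the classic analytic benchmark
objectives (sphere, Rosenbrock, Rastrigin) used to exercise the optimizer.

A toy complex is a concave shell of typed atoms (a spherical pocket with
an opening) around a small branched ligand placed at its center. Shape
complementarity is induced the way real pockets achieve it: hydrogen-bond
acceptor atoms in the shell are placed at matched distances opposite the
ligand's donor groups, and the hydrophobic shell wraps the carbon
skeleton. The planted ("crystal") pose is polished to a local minimum of
the scoring function before being written, and each generated complex is
verified to score below at least 95% of 1000 random poses in its box
(the planted-funnel property).

Only C/N/O-family AD4 types are used, so all scoring branches (gauss,
repulsion, hydrophobic, h-bond) are exercised without exotic elements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import DockingObjective, SearchBox, box_from_pocket
from .ligand import Conformation, LigandModel, apply_conformation
from .optimizer import BoxObjective, bfgs_local_search
from .pdbqt import (
    format_atom_line,
    parse_pdbqt_ligand,
    parse_pdbqt_receptor,
    write_pdbqt_ligand,
)

__all__ = [
    "ToyComplex",
    "ScreeningSet",
    "make_toy_complex",
    "make_test_objective",
    "make_screening_set",
]

#: shell radius of the toy pocket (Angstrom)
_SHELL_RADIUS = 6.0
#: donor-to-acceptor anchor distance placing the h-bond near its optimum
_ANCHOR_DIST = 3.0
#: fraction of random poses the planted pose must beat
_FUNNEL_QUANTILE = 0.95


@dataclass
class ToyComplex:
    """A generated receptor/ligand pair with a planted crystal pose."""

    receptor_pdbqt: str
    ligand_pdbqt: str
    crystal_conformation: Conformation
    box: SearchBox
    seed: int

    @property
    def receptor(self):
        return parse_pdbqt_receptor(self.receptor_pdbqt)

    @property
    def ligand(self) -> LigandModel:
        return parse_pdbqt_ligand(self.ligand_pdbqt)


@dataclass
class ScreeningSet:
    """Shared toy pocket plus labelled active/decoy ligand library."""

    receptor_pdbqt: str
    box: SearchBox
    ligands: dict  # ligand_id -> pdbqt text
    labels: dict  # ligand_id -> "active" | "decoy"

    def labels_csv(self) -> str:
        lines = ["ligand_id,label"]
        lines += [f"{k},{v}" for k, v in sorted(self.labels.items())]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _fibonacci_directions(n: int) -> np.ndarray:
    """n roughly equidistributed unit vectors (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _perp(v: np.ndarray) -> np.ndarray:
    """Some unit vector perpendicular to v."""
    a = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, a)
    return p / np.linalg.norm(p)


def _atom_line(serial, name, ad4_type, xyz, charge=0.0, record="ATOM",
               resname="LIG"):
    from .pdbqt import Atom

    atom = Atom(serial=serial, name=name, ad4_type=ad4_type,
                coords=np.asarray(xyz, float), partial_charge=charge)
    return format_atom_line(atom, record=record, resname=resname)


# ---------------------------------------------------------------------------
# toy receptor / ligand construction
# ---------------------------------------------------------------------------

def _build_ligand_text(rng, n_torsions: int, donor_specs) -> str:
    """Branched heavy-atom ligand with N-H donor arms.

    ``donor_specs`` is a list of (unit direction, radius) pairs; arms of
    different lengths break the arm-swap symmetry so the planted pose is
    the unique way to satisfy all pocket anchors at once. Longer arms get
    a connecting carbon. Each torsion adds a nested two-atom branch (a
    chain carbon plus an off-axis terminal atom, so every torsion
    genuinely moves atoms).
    """
    lines = []
    serial = 0

    def emit(name, t, xyz, charge=0.0):
        nonlocal serial
        serial += 1
        lines.append(_atom_line(serial, f"{name}{serial}", t, xyz, charge))
        return serial, np.asarray(xyz, float)

    lines.append("ROOT")
    _, c0 = emit("C", "C", (0.0, 0.0, 0.0))
    dirs = [np.asarray(u) for u, _ in donor_specs]
    c1_dir = -np.mean(dirs, axis=0) if dirs else np.array([1.0, 0.0, 0.0])
    if np.linalg.norm(c1_dir) < 1e-6:
        c1_dir = np.array([1.0, 0.0, 0.0])
    c1_dir = c1_dir / np.linalg.norm(c1_dir)
    c1_serial, c1 = emit("C", "C", 1.5 * c1_dir)
    for u, radius in donor_specs:
        u = np.asarray(u)
        if radius > 1.9:  # connecting carbon for the long arm
            emit("C", "C", 0.5 * radius * u)
        _, npos = emit("N", "N", radius * u, charge=-0.35)
        emit("H", "HD", npos + 1.0 * u, charge=0.17)
    lines.append("ENDROOT")

    # nested branch chain growing from C1, curling tangentially so the
    # ligand stays compact (inside ~2 A of the pocket center)
    parent_serial, parent_pos = c1_serial, c1
    grow = c1_dir
    open_branches = []
    for b in range(n_torsions):
        t = _perp(grow)
        t = math.cos(0.9) * grow + math.sin(0.9) * (
            math.cos(2.4 * b) * t + math.sin(2.4 * b) * np.cross(grow, t)
        )
        t = t / np.linalg.norm(t)
        child_pos = parent_pos + 1.5 * t
        if np.linalg.norm(child_pos) > 2.2:  # fold back toward the center
            t = -child_pos / np.linalg.norm(child_pos)
            child_pos = parent_pos + 1.5 * t
        lines.append(f"BRANCH {parent_serial:4d} {serial + 1:4d}")
        child_serial, child = emit("C", "C", child_pos)
        side = _perp(t)
        # off-axis terminal N-H donor: its pocket anchor pins the torsion
        # angle of the planted pose (a flipped branch loses the h-bond)
        term = child + 1.4 * (0.8 * side + 0.6 * t)
        _, npos = emit("N", "N", term, charge=-0.35)
        out = npos / np.linalg.norm(npos)
        emit("H", "HD", npos + 1.0 * out, charge=0.17)
        open_branches.append((parent_serial, child_serial))
        parent_serial, parent_pos, grow = child_serial, child, t
    for p, c in reversed(open_branches):
        lines.append(f"ENDBRANCH {p:4d} {c:4d}")
    lines.append(f"TORSDOF {n_torsions}")
    return "\n".join(lines) + "\n"


#: nearest-contact carbon-carbon distance of the shell cast (Angstrom);
#: puts the closest wall atoms just outside steric overlap, in the
#: attractive hydrophobic/gauss region
_CONTACT_DIST = 3.9


def _anchors_clash(anchors, owners, lig_heavy, ligand) -> bool:
    """Reject geometries where an anchor crowds an anchor of a different
    donor or a non-partner ligand atom (would distort the planted pose)."""
    donors = [i for i, a in enumerate(ligand.atoms) if a.is_hbond_donor]
    donor_pos = ligand.ref_coords[donors] if donors else np.zeros((0, 3))
    for k, pos in enumerate(anchors):
        for j, other in enumerate(anchors):
            if owners[j] != owners[k] and np.linalg.norm(pos - other) < 2.8:
                return True
        d = np.linalg.norm(lig_heavy - pos, axis=1)
        partner = np.linalg.norm(donor_pos - pos, axis=1).min() if len(donor_pos) else np.inf
        # nearest non-partner heavy atom must stay outside steric overlap
        if np.sort(d)[1 if np.isclose(d.min(), partner) else 0] < 3.2:
            return True
    return False


def _donor_anchors(ligand: LigandModel):
    """Acceptor-anchor positions for each ligand donor.

    Donors in the rigid ROOT get a *pair* of anchors straddling the N-H
    axis at +-20 degrees (two directional hydrogen bonds lock the rigid
    placement; a displaced or rotated pose typically reaches at most one);
    branch donors get a single anchor, which pins the torsion without
    overcrowding the pocket. Returns ``(positions, owner_indices)``.
    """
    coords = ligand.ref_coords
    hd = np.array(
        [coords[i] for i, a in enumerate(ligand.atoms) if a.ad4_type == "HD"]
    )
    root_set = set(ligand.tree.root_atoms)
    anchors, owners = [], []
    for i, a in enumerate(ligand.atoms):
        if not a.is_hbond_donor:
            continue
        h = hd[np.linalg.norm(hd - coords[i], axis=1).argmin()]
        u = h - coords[i]
        u = u / np.linalg.norm(u)
        if i not in root_set:
            anchors.append(coords[i] + _ANCHOR_DIST * u)
            owners.append(i)
            continue
        w = _perp(u)
        for sign in (1.0, -1.0):
            tilt = math.cos(0.35) * u + sign * math.sin(0.35) * w
            anchors.append(coords[i] + _ANCHOR_DIST * tilt)
            owners.append(i)
    return anchors, owners


def _build_receptor_text(rng, n_pocket_atoms: int, anchor_pos,
                         lig_coords) -> str:
    """Concave shell cast around the planted ligand geometry.

    Shell carbons are placed along cap-removed sphere directions (opening
    toward +z) at the radius where they just graze the ligand's envelope
    (snug shape complementarity: displacing or rotating the ligand either
    breaks contacts or clashes). OA acceptor anchors sit at ``anchor_pos``,
    facing each donor arm at the hydrogen-bond optimum.
    """
    lig_coords = np.asarray(lig_coords, float)
    n_shell = int(n_pocket_atoms)
    cand = _fibonacci_directions(max(2 * n_shell, 16))
    cand = cand[cand[:, 2] < 0.65]  # opening toward +z
    # candidates are z-ordered; subsample evenly so the shell covers the
    # whole cap-removed sphere rather than one band
    idx = np.linspace(0, len(cand) - 1, n_shell).round().astype(int)
    dirs = cand[idx]
    lines = []
    serial = 0
    for u in dirs:
        # start from the ligand envelope along u and push outward until
        # clear of every ligand atom and every anchor
        r = max(4.0, float(np.max(lig_coords @ u)) + 2.0)
        pos = r * u
        for _ in range(40):
            d_lig = np.linalg.norm(lig_coords - pos, axis=1).min()
            d_anc = min(
                (np.linalg.norm(pos - a) for a in anchor_pos), default=np.inf
            )
            if d_lig >= _CONTACT_DIST and d_anc >= 3.2:
                break
            pos = pos + 0.25 * u
        serial += 1
        pos = pos + rng.normal(0.0, 0.08, size=3)
        lines.append(_atom_line(serial, f"C{serial}", "C", pos, 0.1,
                                record="ATOM", resname="POC"))
    for pos in anchor_pos:
        serial += 1
        lines.append(_atom_line(serial, f"O{serial}", "OA", pos, -0.4,
                                record="ATOM", resname="POC"))
    return "\n".join(lines) + "\n"


def _donor_directions(rng, n_donors: int = 2) -> list[np.ndarray]:
    """Well-separated, asymmetric donor directions (break pose symmetry)."""
    base = rng.normal(size=3)
    base[2] = -abs(base[2]) - 0.3  # point into the closed part of the shell
    base = base / np.linalg.norm(base)
    dirs = [base]
    axis = _perp(base)
    for k in range(1, n_donors):
        ang = 1.7 + 0.25 * k  # ~100-110 degrees apart, deliberately uneven
        c, s = math.cos(ang), math.sin(ang)
        rot = c * base + s * (
            math.cos(1.1 * k) * axis + math.sin(1.1 * k) * np.cross(base, axis)
        )
        rot[2] = min(rot[2], 0.4)
        dirs.append(rot / np.linalg.norm(rot))
    return dirs


def _polish(objective, x, f, rounds: int = 8):
    """Repeated full local searches until no further progress."""
    for _ in range(rounds):
        s0, fun, grad, to_x = objective.local_chart(x)
        s, _, _ = bfgs_local_search(fun, grad, s0, max_steps=300)
        x_new = objective.sanitize(to_x(s))
        f_new = objective.value(x_new)
        if f_new < f - 1e-8:
            x, f = x_new, f_new
        else:
            break
    return x, f


def _certify(objective, ligand, x_crystal, f_crystal, cert_rng,
             n_starts: int = 40, n_swarm: int = 3, gap: float = 0.05):
    """Global-minimum check with an energy gap.

    Two probes: full-budget local searches from ``n_starts`` random poses,
    then ``n_swarm`` independent swarm searches. A deeper solution within
    1 A heavy-atom RMSD of the crystal replaces it (same basin, better
    polished). Any probe further away must score at least ``gap`` above
    the crystal — otherwise affinity ranking between repeated searches
    could flip to the wrong pose, and the geometry is rejected.
    """
    from .ligand import rmsd as _rmsd
    from .optimizer import SwarmConfig, pso_search

    heavy = ligand.heavy_indices
    budget = 10 * objective.dim + 30
    crys_coords = objective._energy_at(x_crystal)[1][heavy]

    def consider(xf, f):
        nonlocal x_crystal, f_crystal, crys_coords
        if f >= f_crystal + gap:
            return True
        coords = objective._energy_at(xf)[1][heavy]
        if _rmsd(coords, crys_coords) <= 1.0:
            if f < f_crystal:
                x_crystal, f_crystal = _polish(objective, xf, f)
                crys_coords = objective._energy_at(x_crystal)[1][heavy]
            return True
        return False

    for _ in range(n_starts):
        x = objective.sanitize(objective.random_point(cert_rng))
        s0, fun, grad, to_x = objective.local_chart(x)
        s, _, _ = bfgs_local_search(fun, grad, s0, max_steps=budget)
        xf = objective.sanitize(to_x(s))
        if not consider(xf, objective.value(xf)):
            return x_crystal, f_crystal, False
    for _ in range(n_swarm):
        cfg = SwarmConfig(seed=int(cert_rng.integers(2**31)))
        xf, f, _ = pso_search(objective, cfg)
        if not consider(objective.sanitize(xf), f):
            return x_crystal, f_crystal, False
    return x_crystal, f_crystal, True


def make_toy_complex(n_pocket_atoms: int = 24, n_torsions: int = 0,
                     seed: int = 0) -> ToyComplex:
    """Generate a seed-deterministic toy complex with a planted pose.

    The ligand is polished to the nearest local minimum of the scoring
    function before its coordinates are written, so the stored crystal
    pose is exactly reproducible from the file. Raises if no geometry
    satisfying the planted-funnel property is found in 100 attempts.
    """
    if n_pocket_atoms < 8:
        raise ValueError("n_pocket_atoms must be >= 8")
    if not 0 <= n_torsions <= 10:
        raise ValueError("n_torsions must lie in [0, 10]")
    rng = np.random.default_rng(seed)

    for _attempt in range(100):
        donor_dirs = _donor_directions(rng, n_donors=2)
        # unequal arm lengths: a swapped pose leaves one anchor unreachable
        donor_specs = [(donor_dirs[0], 1.5), (donor_dirs[1], 2.3)]
        ligand_text = _build_ligand_text(rng, n_torsions, donor_specs)
        try:
            ligand = parse_pdbqt_ligand(ligand_text)
            lig_heavy = ligand.ref_coords[ligand.heavy_indices]
            anchors, owners = _donor_anchors(ligand)
            if _anchors_clash(anchors, owners, lig_heavy, ligand):
                continue
            receptor_text = _build_receptor_text(
                rng, n_pocket_atoms, anchors, lig_heavy
            )
            receptor = parse_pdbqt_receptor(receptor_text)
        except Exception:  # malformed geometry attempt; try again
            continue
        box = box_from_pocket([a for a in receptor if a.is_heavy])
        objective = DockingObjective(receptor, ligand, box)

        # polish the planted pose to the nearest scoring minimum; repeat
        # until the local search makes no further progress
        x_crystal = ligand.reference_conformation().to_vector()
        f_crystal = objective.value(x_crystal)
        x_crystal, f_crystal = _polish(objective, x_crystal, f_crystal)

        # certification: the planted pose must be the global minimum as
        # seen by multi-start full-budget local searches. Same-basin
        # improvements (RMSD <= 1 A) are adopted as the crystal; a deeper
        # minimum elsewhere rejects this geometry.
        x_crystal, f_crystal, certified = _certify(
            objective, ligand, x_crystal, f_crystal,
            np.random.default_rng(rng.integers(2**31)),
        )
        if not certified:
            continue

        conf = Conformation.from_vector(x_crystal)
        coords = apply_conformation(ligand, conf)
        ligand_text = write_pdbqt_ligand(ligand, coords=coords)
        ligand = parse_pdbqt_ligand(ligand_text)
        objective = DockingObjective(receptor, ligand, box)
        crystal_conf = ligand.reference_conformation()
        f_crystal = objective.value(crystal_conf.to_vector())

        # planted-funnel verification
        pose_rng = np.random.default_rng(rng.integers(2**31))
        samples = np.array(
            [objective.value(objective.random_point(pose_rng)) for _ in range(1000)]
        )
        threshold = np.quantile(samples, 1.0 - _FUNNEL_QUANTILE)
        if f_crystal < min(threshold, 0.0):
            return ToyComplex(
                receptor_pdbqt=receptor_text,
                ligand_pdbqt=ligand_text,
                crystal_conformation=crystal_conf,
                box=box,
                seed=seed,
            )
    raise RuntimeError(
        f"no feasible toy complex geometry after 100 attempts (seed={seed})"
    )


# ---------------------------------------------------------------------------
# analytic optimizer test objectives
# ---------------------------------------------------------------------------

class _AnalyticObjective(BoxObjective):
    def __init__(self, dim, lower, upper, value_fn, grad_fn, minimum_x,
                 minimum_value, name):
        super().__init__(dim, lower, upper)
        self._value_fn = value_fn
        self._grad_fn = grad_fn
        self.minimum_x = np.asarray(minimum_x, float)
        self.minimum_value = float(minimum_value)
        self.name = name

    def value(self, x):
        return float(self._value_fn(np.asarray(x, float)))

    def gradient(self, x):
        return np.asarray(self._grad_fn(np.asarray(x, float)), float)


def make_test_objective(name: str, dim: int = 2, bounds=None,
                        center=None) -> _AnalyticObjective:
    """Analytic objective with known global minimum and exact gradient.

    ``sphere`` (optionally shifted to ``center``), ``rosenbrock`` and
    ``rastrigin`` with their conventional domains.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if name == "sphere":
        lo, hi = bounds if bounds is not None else (-5.0, 5.0)
        c = np.full(dim, 0.5 * (np.mean(lo) + np.mean(hi))) if center is None else (
            np.broadcast_to(np.asarray(center, float), (dim,)).copy()
        )
        return _AnalyticObjective(
            dim, lo, hi,
            lambda x: np.sum((x - c) ** 2),
            lambda x: 2.0 * (x - c),
            c, 0.0, "sphere",
        )
    if name == "rosenbrock":
        lo, hi = bounds if bounds is not None else (-2.048, 2.048)

        def rosen(x):
            return np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2)

        def rosen_grad(x):
            g = np.zeros_like(x)
            g[:-1] = -400.0 * x[:-1] * (x[1:] - x[:-1] ** 2) - 2.0 * (1.0 - x[:-1])
            g[1:] += 200.0 * (x[1:] - x[:-1] ** 2)
            return g

        return _AnalyticObjective(
            dim, lo, hi, rosen, rosen_grad, np.ones(dim), 0.0, "rosenbrock"
        )
    if name == "rastrigin":
        lo, hi = bounds if bounds is not None else (-5.12, 5.12)
        return _AnalyticObjective(
            dim, lo, hi,
            lambda x: 10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)),
            lambda x: 2.0 * x + 20.0 * np.pi * np.sin(2.0 * np.pi * x),
            np.zeros(dim), 0.0, "rastrigin",
        )
    raise ValueError(f"unknown test objective {name!r}")


# ---------------------------------------------------------------------------
# screening set
# ---------------------------------------------------------------------------

def _screening_ligand_text(rng, donor_specs, jitter: float) -> str:
    """Rigid screening compound: carbon core plus N-H donor arms of the
    given (direction, radius) geometry."""
    lines = ["ROOT"]
    serial = 0

    def emit(name, t, xyz, charge=0.0):
        nonlocal serial
        serial += 1
        lines.append(_atom_line(serial, f"{name}{serial}", t, xyz, charge))

    dirs = [np.asarray(u) for u, _ in donor_specs]
    emit("C", "C", rng.normal(0.0, jitter, size=3))
    core_dir = -np.mean(dirs, axis=0)
    if np.linalg.norm(core_dir) < 1e-6:
        core_dir = np.array([1.0, 0.0, 0.0])
    core_dir = core_dir / np.linalg.norm(core_dir)
    emit("C", "C", 1.5 * core_dir + rng.normal(0.0, jitter, size=3))
    for u, radius in donor_specs:
        u = np.asarray(u)
        npos = radius * u + rng.normal(0.0, jitter, size=3)
        emit("N", "N", npos, charge=-0.35)
        emit("H", "HD", npos + 1.0 * u, charge=0.17)
    lines.append("ENDROOT")
    lines.append("TORSDOF 0")
    return "\n".join(lines) + "\n"


def _rotate_toward(u, target, angle):
    """Rotate unit vector u by ``angle`` radians toward ``target``."""
    u = np.asarray(u, float)
    t = np.asarray(target, float)
    axis = np.cross(u, t)
    n = np.linalg.norm(axis)
    if n < 1e-9:
        axis = _perp(u)
    else:
        axis = axis / n
    c, s = math.cos(angle), math.sin(angle)
    return c * u + s * np.cross(axis, u) + (1 - c) * (axis @ u) * axis


def make_screening_set(n_actives: int = 8, n_decoys: int = 8,
                       separation: float = 1.0, seed: int = 0) -> ScreeningSet:
    """Toy actives/decoys library over a shared pocket.

    Actives carry three donor arms whose lengths match the pocket's
    acceptor-anchor distances; decoys have identical composition (same
    atom counts and types) but arm lengths detuned by ``separation``
    (0 = indistinguishable from actives, 1 = fully detuned), so their
    donors either fall short of the hydrogen-bond range or clash with the
    anchors, whatever the rigid-body placement.
    """
    if n_actives < 1 or n_decoys < 1:
        raise ValueError("need at least one active and one decoy")
    if not 0.0 <= separation <= 1.0:
        raise ValueError("separation must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    donor_dirs = _donor_directions(rng, n_donors=3)
    active_specs = [(u, 1.5) for u in donor_dirs]
    template = parse_pdbqt_ligand(
        _screening_ligand_text(np.random.default_rng(seed), active_specs, jitter=0.0)
    )
    receptor_text = _build_receptor_text(
        rng, 30, _donor_anchors(template)[0],
        template.ref_coords[template.heavy_indices],
    )
    receptor = parse_pdbqt_receptor(receptor_text)
    box = box_from_pocket([a for a in receptor if a.is_heavy])

    # arm-length detuning at separation = 1 (Angstrom): short arms miss
    # the h-bond ramp, long arms clash with their anchor
    detune = (-0.7, 0.8, -0.7)
    ligands, labels = {}, {}
    for i in range(n_actives):
        lid = f"active_{i:03d}"
        ligands[lid] = _screening_ligand_text(rng, active_specs, jitter=0.05)
        labels[lid] = "active"
    for i in range(n_decoys):
        lid = f"decoy_{i:03d}"
        decoy_specs = [
            (u, 1.5 + separation * d) for (u, _), d in zip(active_specs, detune)
        ]
        ligands[lid] = _screening_ligand_text(rng, decoy_specs, jitter=0.05)
        labels[lid] = "decoy"
    return ScreeningSet(
        receptor_pdbqt=receptor_text, box=box, ligands=ligands, labels=labels
    )
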