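"""Reading and writing AutoDock PDBQT files.

PDBQT extends the PDB atom record with a Gasteiger partial charge and an
AD4 atom-type token, and (for ligands) wraps the atoms in a ROOT /
BRANCH torsion tree that declares the rotatable bonds. This module parses
prepared files (it does not assign charges, types or protonation) into
:class:`Atom` lists and :class:`~chaosdock.ligand.LigandModel` objects,
and writes them back, including multi-model ranked pose output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Atom",
    "PDBQTError",
    "AD4_TYPES",
    "parse_pdbqt_ligand",
    "parse_pdbqt_receptor",
    "write_pdbqt_ligand",
    "write_poses_pdbqt",
]


class PDBQTError(ValueError):
    """Malformed PDBQT content (message names the offending line)."""


# AD4 atom types consumed by the engine: token -> (vdW radius in Angstrom,
# hydrophobic, h-bond acceptor, is hydrogen). Radii follow the Vina "xs"
# set. Donor status is geometric (polar heavy atom carrying an HD) and is
# assigned after parsing, not from the type alone.
AD4_TYPES: dict[str, tuple[float, bool, bool, bool]] = {
    "C": (1.9, True, False, False),
    "A": (1.9, True, False, False),
    "N": (1.8, False, False, False),
    "NA": (1.8, False, True, False),
    "NS": (1.8, False, True, False),
    "O": (1.7, False, True, False),
    "OA": (1.7, False, True, False),
    "OS": (1.7, False, True, False),
    "S": (2.0, False, False, False),
    "SA": (2.0, False, True, False),
    "P": (2.1, False, False, False),
    "F": (1.5, True, False, False),
    "Cl": (1.8, True, False, False),
    "CL": (1.8, True, False, False),
    "Br": (2.0, True, False, False),
    "BR": (2.0, True, False, False),
    "I": (2.2, True, False, False),
    "H": (0.0, False, False, True),
    "HD": (0.0, False, False, True),
    "HS": (0.0, False, False, True),
    "Zn": (1.2, False, False, False),
    "ZN": (1.2, False, False, False),
    "Mg": (1.2, False, False, False),
    "MG": (1.2, False, False, False),
    "Mn": (1.2, False, False, False),
    "MN": (1.2, False, False, False),
    "Ca": (1.2, False, False, False),
    "CA": (1.2, False, False, False),
    "Fe": (1.2, False, False, False),
    "FE": (1.2, False, False, False),
}

#: maximum donor-hydrogen to heavy-atom distance (Angstrom) used to flag
#: hydrogen-bond donors
_DONOR_H_DIST = 1.3


@dataclass
class Atom:
    """One PDBQT atom: identity, coordinates, charge and derived flags."""

    serial: int
    name: str
    ad4_type: str
    coords: np.ndarray  # (3,) Angstrom
    partial_charge: float = 0.0
    is_hydrophobic: bool = False
    is_hbond_donor: bool = False
    is_hbond_acceptor: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise PDBQTError(f"atom {self.serial}: coordinates must be 3 finite reals")
        if not self.ad4_type:
            raise PDBQTError(f"atom {self.serial}: empty AD4 type")
        radius, hydrophobic, acceptor, _ = _lookup_type(self.ad4_type, self.serial)
        self.is_hydrophobic = hydrophobic
        self.is_hbond_acceptor = acceptor

    @property
    def radius(self) -> float:
        return AD4_TYPES[self.ad4_type][0]

    @property
    def is_hydrogen(self) -> bool:
        return AD4_TYPES[self.ad4_type][3]

    @property
    def is_heavy(self) -> bool:
        return not self.is_hydrogen


def _lookup_type(token: str, serial) -> tuple[float, bool, bool, bool]:
    try:
        return AD4_TYPES[token]
    except KeyError:
        raise PDBQTError(
            f"atom {serial}: unrecognized AD4 atom type {token!r} "
            f"(known: {sorted(AD4_TYPES)})"
        ) from None


def _parse_atom_line(line: str, lineno: int) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError):
        raise PDBQTError(f"line {lineno}: malformed ATOM/HETATM record") from None
    # Tail past the coordinate block varies between preparation tools;
    # take the last whitespace token as the AD4 type and the one before it
    # as the partial charge.
    tail = line[54:].split()
    if len(tail) < 2:
        raise PDBQTError(f"line {lineno}: missing partial charge / AD4 type fields")
    ad4_type = tail[-1]
    try:
        charge = float(tail[-2])
    except ValueError:
        raise PDBQTError(f"line {lineno}: unparseable partial charge {tail[-2]!r}") from None
    _lookup_type(ad4_type, serial)
    return Atom(serial=serial, name=name, ad4_type=ad4_type,
                coords=np.array([x, y, z]), partial_charge=charge)


def _assign_donors(atoms: list[Atom]) -> None:
    """Flag polar heavy atoms bonded to a polar hydrogen (HD) as donors."""
    h_coords = [a.coords for a in atoms if a.ad4_type in ("HD", "HS")]
    if not h_coords:
        return
    h_coords = np.array(h_coords)
    for a in atoms:
        if a.is_heavy and a.ad4_type[0] in ("N", "O", "S"):
            d = np.linalg.norm(h_coords - a.coords, axis=1)
            if np.any(d < _DONOR_H_DIST):
                a.is_hbond_donor = True


def _read_text(source) -> str:
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and source.endswith(".pdbqt")
    ):
        return Path(source).read_text()
    return source


def parse_pdbqt_ligand(source):
    """Parse a ligand PDBQT (path or text) into a :class:`LigandModel`.

    The ROOT block defines the rigid core; each BRANCH record opens a
    rotatable bond (parent serial, child serial) whose nested atoms form
    the moved set. Nesting must balance; atoms must fall inside a
    ROOT/BRANCH scope.
    """
    from .ligand import LigandModel, TorsionBranch, TorsionTree

    text = _read_text(source)
    atoms: list[Atom] = []
    serial_to_idx: dict[int, int] = {}
    root_ids: list[int] = []
    branches: list[dict] = []  # {"parent": serial, "child": serial, "moved": [idx]}
    layout: list[tuple] = []
    open_stack: list[int | None] = []  # None = ROOT scope, int = branch index
    seen_root = False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        rec = raw[:6].strip()
        if rec in ("ATOM", "HETATM"):
            if not open_stack:
                raise PDBQTError(f"line {lineno}: atom outside ROOT/BRANCH scope")
            atom = _parse_atom_line(raw, lineno)
            idx = len(atoms)
            atoms.append(atom)
            serial_to_idx[atom.serial] = idx
            layout.append(("ATOM", idx))
            scope = open_stack[-1]
            if scope is None:
                root_ids.append(idx)
            for b in open_stack:
                if b is not None:
                    branches[b]["moved"].append(idx)
        elif raw.startswith("ROOT"):
            if seen_root:
                raise PDBQTError(f"line {lineno}: duplicate ROOT")
            seen_root = True
            open_stack.append(None)
            layout.append(("ROOT",))
        elif raw.startswith("ENDROOT"):
            if not open_stack or open_stack[-1] is not None:
                raise PDBQTError(f"line {lineno}: ENDROOT without matching ROOT")
            open_stack.pop()
            layout.append(("ENDROOT",))
        elif raw.startswith("BRANCH"):
            parts = raw.split()
            if len(parts) != 3:
                raise PDBQTError(f"line {lineno}: BRANCH needs two atom serials")
            b = {"parent": int(parts[1]), "child": int(parts[2]), "moved": []}
            branches.append(b)
            open_stack.append(len(branches) - 1)
            layout.append(("BRANCH", len(branches) - 1))
        elif raw.startswith("ENDBRANCH"):
            if not open_stack or open_stack[-1] is None:
                raise PDBQTError(f"line {lineno}: ENDBRANCH without matching BRANCH")
            layout.append(("ENDBRANCH", open_stack.pop()))
        # REMARK / TER / TORSDOF / MODEL / ENDMDL and blank lines are ignored
    if open_stack:
        raise PDBQTError("unbalanced ROOT/BRANCH nesting: unclosed block at end of file")
    if not seen_root:
        raise PDBQTError("ligand PDBQT lacks a ROOT block")
    if not atoms:
        raise PDBQTError("ligand PDBQT contains no atoms")

    _assign_donors(atoms)
    tree_branches = []
    for b in branches:
        for key in ("parent", "child"):
            if b[key] not in serial_to_idx:
                raise PDBQTError(
                    f"BRANCH references unknown atom serial {b[key]}"
                )
        tree_branches.append(
            TorsionBranch(
                parent=serial_to_idx[b["parent"]],
                child=serial_to_idx[b["child"]],
                moved=tuple(b["moved"]),
            )
        )
    tree = TorsionTree(root_atoms=tuple(root_ids), branches=tuple(tree_branches))
    return LigandModel(atoms=atoms, tree=tree, layout=tuple(layout))


def parse_pdbqt_receptor(source) -> list[Atom]:
    """Parse a rigid receptor PDBQT into a flat atom list (no tree)."""
    text = _read_text(source)
    atoms: list[Atom] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        rec = raw[:6].strip()
        if rec in ("ATOM", "HETATM"):
            atoms.append(_parse_atom_line(raw, lineno))
    if not atoms:
        raise PDBQTError("receptor PDBQT contains no atoms")
    _assign_donors(atoms)
    return atoms


def format_atom_line(atom: Atom, coords=None, record: str = "ATOM",
                     resname: str = "LIG") -> str:
    x, y, z = atom.coords if coords is None else coords
    return (
        f"{record:<6s}{atom.serial:5d} {atom.name:<4s} {resname:<3s} A   1    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}    "
        f"{atom.partial_charge:6.3f} {atom.ad4_type:<2s}"
    )


def write_pdbqt_ligand(model, coords=None) -> str:
    """Serialize a ligand model (optionally with replacement coordinates)
    back to PDBQT text, preserving its ROOT/BRANCH layout."""
    lines = []
    for token in model.layout:
        kind = token[0]
        if kind == "ATOM":
            idx = token[1]
            xyz = None if coords is None else coords[idx]
            lines.append(format_atom_line(model.atoms[idx], xyz))
        elif kind == "ROOT":
            lines.append("ROOT")
        elif kind == "ENDROOT":
            lines.append("ENDROOT")
        elif kind == "BRANCH":
            b = model.tree.branches[token[1]]
            lines.append(
                f"BRANCH {model.atoms[b.parent].serial:4d} {model.atoms[b.child].serial:4d}"
            )
        elif kind == "ENDBRANCH":
            b = model.tree.branches[token[1]]
            lines.append(
                f"ENDBRANCH {model.atoms[b.parent].serial:4d} {model.atoms[b.child].serial:4d}"
            )
    lines.append(f"TORSDOF {model.n_torsions}")
    return "\n".join(lines) + "\n"


def write_poses_pdbqt(model, poses) -> str:
    """Multi-model PDBQT for a ranked pose list.

    Each pose carries a ``REMARK VINA RESULT`` line with its predicted
    affinity (kcal/mol); the RMSD columns are placeholders as the reference
    pose is in general unknown at docking time.
    """
    blocks = []
    for i, pose in enumerate(poses, start=1):
        body = write_pdbqt_ligand(model, coords=pose.coordinates).rstrip("\n")
        blocks.append(
            f"MODEL {i}\n"
            f"REMARK VINA RESULT: {pose.affinity:9.3f} {0.0:9.3f} {0.0:9.3f}\n"
            f"{body}\nENDMDL"
        )
    return "\n".join(blocks) + "\n"
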