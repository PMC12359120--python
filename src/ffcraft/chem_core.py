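"""Molecular structure representation and geometry manipulation.

The :class:`Molecule` container holds element symbols, Cartesian
coordinates in Å, formal charge, spin multiplicity and an undirected
bond graph over 0-based atom indices. File I/O covers the XYZ format
(read and write) and a minimal PDB subset (ATOM/HETATM coordinates and
element column). Connectivity is perceived from covalent radii; torsion
angles follow the IUPAC sign convention (positive counter-clockwise
looking down the j->k axis).

Atom indices are 0-based throughout the library; the command-line layer
converts to and from the 1-based labels chemists print.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data import COVALENT_RADII, atomic_mass, covalent_radius


class ParseError(ValueError):
    """Raised for malformed structure files; carries the offending line/frame."""


class GeometryError(ValueError):
    """Raised for geometrically ill-defined requests (ring rotations, collinear torsions)."""


@dataclass
class Molecule:
    elements: list[str]
    coordinates: np.ndarray  # (N, 3) Å
    formal_charge: int = 0
    multiplicity: int = 1
    bonds: set[tuple[int, int]] = field(default_factory=set)
    comment: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        if len(self.elements) != len(self.coordinates):
            raise ValueError("element and coordinate counts differ")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        for e in self.elements:
            if e not in COVALENT_RADII:
                raise ValueError(f"unknown element symbol '{e}'")
        self.bonds = {canonical_bond(a, b) for a, b in self.bonds}
        n = self.natoms
        for a, b in self.bonds:
            if a == b:
                raise ValueError(f"self-bond on atom {a}")
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"bond ({a},{b}) references a missing atom")

    @property
    def natoms(self) -> int:
        return len(self.elements)

    @property
    def masses(self) -> np.ndarray:
        return np.array([atomic_mass(e) for e in self.elements])

    def copy(self) -> "Molecule":
        return Molecule(
            list(self.elements),
            self.coordinates.copy(),
            self.formal_charge,
            self.multiplicity,
            set(self.bonds),
            self.comment,
        )

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.natoms))
        g.add_edges_from(self.bonds)
        return g

    def neighbors(self, i: int) -> list[int]:
        out = [b if a == i else a for a, b in self.bonds if i in (a, b)]
        return sorted(out)


@dataclass(frozen=True)
class RotatableBond:
    """An acyclic single bond whose rotation generates distinct conformers.

    ``multiplicity`` counts the torsional minima of the rotor (3 for a bond
    between two sp3 centers, 2 when either end is sp2/planar).
    """

    axis: tuple[int, int]
    reference_dihedral: tuple[int, int, int, int]
    multiplicity: int


def canonical_bond(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


# ---------------------------------------------------------------------------
# XYZ / PDB I/O


def read_xyz(text: str) -> Molecule:
    """Parse an XYZ-format string into a Molecule (no bonds perceived)."""
    lines = text.splitlines()
    if not lines:
        raise ParseError("empty xyz input")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise ParseError(f"line 1: expected integer atom count, got '{lines[0].strip()}'")
    if len(lines) < n + 2:
        raise ParseError(f"expected {n} atom lines, file ends after {max(len(lines) - 2, 0)}")
    comment = lines[1] if len(lines) > 1 else ""
    elements: list[str] = []
    coords: list[list[float]] = []
    for k in range(n):
        lineno = k + 3
        parts = lines[k + 2].split()
        if len(parts) < 4:
            raise ParseError(f"line {lineno}: expected 'element x y z'")
        sym = parts[0].capitalize()
        if sym not in COVALENT_RADII:
            raise ParseError(f"line {lineno}: unknown element '{parts[0]}'")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise ParseError(f"line {lineno}: non-numeric coordinate")
        elements.append(sym)
        coords.append(xyz)
    # trailing non-blank atom-like lines indicate a count mismatch
    for extra in lines[n + 2 :]:
        if extra.split():
            raise ParseError(f"header declares {n} atoms but extra atom lines follow")
    return Molecule(elements, np.array(coords), comment=comment.strip())


def read_xyz_file(path) -> Molecule:
    with open(path) as fh:
        return read_xyz(fh.read())


def write_xyz(mol: Molecule, comment: str | None = None) -> str:
    lines = [str(mol.natoms), comment if comment is not None else mol.comment]
    for e, (x, y, z) in zip(mol.elements, mol.coordinates):
        lines.append(f"{e:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    return "\n".join(lines) + "\n"


def write_xyz_file(mol: Molecule, path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(write_xyz(mol, comment))


def read_pdb(text: str) -> Molecule:
    """Read ATOM/HETATM records: coordinates plus the element column only."""
    elements: list[str] = []
    coords: list[list[float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        try:
            xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        except (ValueError, IndexError):
            raise ParseError(f"line {lineno}: malformed coordinates in PDB record")
        sym = line[76:78].strip().capitalize()
        if not sym:
            # fall back to the first letter(s) of the atom name
            name = line[12:16].strip()
            sym = "".join(c for c in name if c.isalpha())[:2].capitalize()
            if sym not in COVALENT_RADII:
                sym = sym[:1]
        if sym not in COVALENT_RADII:
            raise ParseError(f"line {lineno}: unknown element '{sym}'")
        elements.append(sym)
        coords.append(xyz)
    if not elements:
        raise ParseError("no ATOM/HETATM records found")
    return Molecule(elements, np.array(coords))


def read_pdb_file(path) -> Molecule:
    with open(path) as fh:
        return read_pdb(fh.read())


# ---------------------------------------------------------------------------
# Connectivity


def perceive_bonds(mol: Molecule, tolerance: float = 1.3) -> Molecule:
    """Assign bonds where the distance falls below ``tolerance`` x sum of covalent radii.

    Returns the same molecule with ``bonds`` replaced. Distances below
    0.4 Å indicate overlapping atoms and raise :class:`GeometryError`.
    """
    n = mol.natoms
    if n < 2:
        mol.bonds = set()
        return mol
    dmat = squareform(pdist(mol.coordinates))
    radii = np.array([covalent_radius(e) for e in mol.elements])
    bonds: set[tuple[int, int]] = set()
    for a in range(n):
        for b in range(a + 1, n):
            d = dmat[a, b]
            if d < 0.4:
                raise GeometryError(f"atoms {a} and {b} overlap (d = {d:.3f} Å)")
            if d <= tolerance * (radii[a] + radii[b]):
                bonds.add((a, b))
    mol.bonds = bonds
    return mol


# ---------------------------------------------------------------------------
# Dihedral angles


def _check_quad(mol: Molecule, quad: Sequence[int]) -> tuple[int, int, int, int]:
    i, j, k, l = quad
    if len({i, j, k, l}) != 4:
        raise ValueError(f"dihedral atoms must be distinct, got {quad}")
    for pair in ((i, j), (j, k), (k, l)):
        if canonical_bond(*pair) not in mol.bonds:
            raise ValueError(f"atoms {pair} of dihedral {tuple(quad)} are not bonded")
    return i, j, k, l


def dihedral_from_coordinates(x: np.ndarray, quad: Sequence[int]) -> float:
    """Torsion angle in degrees, IUPAC sign, from a coordinate matrix."""
    i, j, k, l = quad
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError(f"dihedral {tuple(quad)} undefined: collinear atoms")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))
    # map -180 -> +180 so the range is (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def get_dihedral_in_degrees(mol: Molecule, quad: Sequence[int]) -> float:
    quad = _check_quad(mol, quad)
    return dihedral_from_coordinates(mol.coordinates, quad)


def _rotation_side(mol: Molecule, j: int, k: int) -> set[int]:
    """Atoms on the k side after deleting bond j-k; error if j-k lies in a ring."""
    g = mol.graph()
    g.remove_edge(j, k)
    if nx.has_path(g, j, k):
        raise GeometryError(f"bond ({j},{k}) is in a ring; rotation is ill-defined")
    return nx.node_connected_component(g, k)


def set_dihedral_in_degrees(mol: Molecule, quad: Sequence[int], value: float) -> Molecule:
    """Rotate the fragment on the l side of the j-k axis so the torsion equals ``value``.

    Atoms on the i side keep their coordinates bitwise; rigid rotation
    preserves all distances within each fragment.
    """
    i, j, k, l = _check_quad(mol, quad)
    current = dihedral_from_coordinates(mol.coordinates, (i, j, k, l))
    # rotating the k-side by +delta about the j->k axis decreases the
    # IUPAC-signed torsion, hence the sign
    delta = np.radians(current - value)
    moving = _rotation_side(mol, j, k)
    axis = mol.coordinates[k] - mol.coordinates[j]
    axis = axis / np.linalg.norm(axis)
    # Rodrigues rotation about the j->k axis through atom j
    c, s = np.cos(delta), np.sin(delta)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + s * K + (1 - c) * (K @ K)
    origin = mol.coordinates[j]
    idx = sorted(moving)
    mol.coordinates[idx] = (mol.coordinates[idx] - origin) @ R.T + origin
    return mol


def angles_from_bonds(mol: Molecule) -> list[tuple[int, int, int]]:
    """All a-b-c angle triples implied by the bond graph, deterministic order."""
    out = []
    for b in range(mol.natoms):
        nbrs = mol.neighbors(b)
        for ia in range(len(nbrs)):
            for ic in range(ia + 1, len(nbrs)):
                out.append((nbrs[ia], b, nbrs[ic]))
    return out


def dihedrals_from_bonds(mol: Molecule) -> list[tuple[int, int, int, int]]:
    """All proper i-j-k-l torsions over bonded quadruples, deterministic order."""
    out = []
    for j, k in sorted(mol.bonds):
        for i in mol.neighbors(j):
            if i == k:
                continue
            for l in mol.neighbors(k):
                if l == j or l == i:
                    continue
                out.append((i, j, k, l))
    return out


# ---------------------------------------------------------------------------
# Rotatable bonds


def _is_ring_bond(g: nx.Graph, a: int, b: int) -> bool:
    g2 = g.copy()
    g2.remove_edge(a, b)
    return nx.has_path(g2, a, b)


def _hybridization_multiplicity(mol: Molecule, j: int, k: int) -> int:
    """3 if both ends are sp3 (4 neighbors), otherwise 2 (sp2/planar end)."""
    nj = len(mol.neighbors(j))
    nk = len(mol.neighbors(k))
    return 3 if (nj == 4 and nk == 4) else 2


def _is_methyl_rotor(mol: Molecule, center: int, axis_partner: int) -> bool:
    nbrs = [n for n in mol.neighbors(center) if n != axis_partner]
    return (
        mol.elements[center] == "C"
        and len(nbrs) == 3
        and all(mol.elements[n] == "H" for n in nbrs)
    )


def detect_rotatable_bonds(mol: Molecule, exclude_methyl: bool = True) -> list[RotatableBond]:
    """Enumerate acyclic single bonds between non-terminal atoms.

    With ``exclude_methyl`` the bonds whose rotation only spins a CH3
    group are dropped. Each bond carries a reference dihedral (lowest-index
    neighbors on either side) and a torsional multiplicity from the
    neighbor-count hybridization rule.
    """
    g = mol.graph()
    out: list[RotatableBond] = []
    for j, k in sorted(mol.bonds):
        nj = [n for n in mol.neighbors(j) if n != k]
        nk = [n for n in mol.neighbors(k) if n != j]
        if not nj or not nk:
            continue  # terminal bond
        if _is_ring_bond(g, j, k):
            continue
        if exclude_methyl and (_is_methyl_rotor(mol, j, k) or _is_methyl_rotor(mol, k, j)):
            continue
        quad = (min(nj), j, k, min(nk))
        out.append(RotatableBond((j, k), quad, _hybridization_multiplicity(mol, j, k)))
    return out
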