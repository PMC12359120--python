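"""Geometric solvation of a solute in a cubic box.

Solvent molecules are inserted by random batch placement with a k-d
tree overlap check until the target count — derived from the requested
density and the solvent-accessible volume of the box — is reached.
Counterions (Na+ or Cl-) neutralize charged solutes, and the Galvani
surface-potential registry corrects ionic solvation free energies by
-q*phi_G (phi_G = -57.7 kJ/mol per unit charge for SPC/E water).
Writers produce GROMACS .gro / PDB coordinates and a .top counts
section.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .chem_core import Molecule
from .data import atomic_mass, vdw_radius

DEFAULT_PADDING_NM = 1.0
DEFAULT_OVERLAP_CUTOFF = 1.8  # Å between atoms of different molecules

# Galvani surface potential phi_G in kJ/mol per unit charge, by water model
GALVANI_POTENTIALS = {"SPC/E": -57.7}

_ION_SPECIES = {"Na+": ("Na", +1), "Cl-": ("Cl", -1)}


class PackingError(RuntimeError):
    """Insertion failed to reach the requested density/counts."""


def _water_template(name: str) -> Molecule:
    """Rigid three-site water geometries (O at origin, bisector on +x)."""
    if name == "SPC/E":
        r_oh, theta = 1.0, math.radians(109.47)
    elif name == "TIP3P":
        r_oh, theta = 0.9572, math.radians(104.52)
    else:
        raise KeyError(name)
    half = theta / 2.0
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [r_oh * math.cos(half), r_oh * math.sin(half), 0.0],
            [r_oh * math.cos(half), -r_oh * math.sin(half), 0.0],
        ]
    )
    mol = Molecule(["O", "H", "H"], coords, bonds={(0, 1), (0, 2)})
    mol.comment = name
    return mol


WATER_CHARGES = {"SPC/E": (-0.8476, 0.4238), "TIP3P": (-0.834, 0.417)}


@dataclass
class SolventSpec:
    """A solvent template with its target liquid density."""

    template: Molecule
    density: float  # g/cm^3
    name: str = "solvent"

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.template.natoms < 1:
            raise ValueError("solvent template has no atoms")

    @property
    def molecular_mass(self) -> float:
        return float(sum(atomic_mass(e) for e in self.template.elements))

    @classmethod
    def water(cls, model: str = "SPC/E") -> "SolventSpec":
        return cls(_water_template(model), density=0.997, name=model)


@dataclass
class SolvatedSystem:
    solute: Molecule
    solvent_template: Molecule
    solvent_positions: list[np.ndarray]  # coordinates of each replica, (n_t, 3) Å
    ions: list[tuple[str, np.ndarray]] = field(default_factory=list)
    box_edge: float = 0.0  # Å, cubic
    solvent_name: str = "SOL"

    @property
    def n_solvent(self) -> int:
        return len(self.solvent_positions)

    @property
    def n_atoms(self) -> int:
        return (
            self.solute.natoms
            + self.n_solvent * self.solvent_template.natoms
            + len(self.ions)
        )

    def all_coordinates(self) -> np.ndarray:
        parts = [self.solute.coordinates]
        parts.extend(self.solvent_positions)
        parts.extend(pos.reshape(1, 3) for _, pos in self.ions)
        return np.vstack(parts) if parts else np.empty((0, 3))

    @property
    def net_charge(self) -> int:
        q = self.solute.formal_charge
        for species, _ in self.ions:
            q += _ION_SPECIES[species][1]
        return q


def solute_volume(mol: Molecule) -> float:
    """Summed van der Waals sphere volume in Å^3 (no overlap correction)."""
    return float(sum(4.0 / 3.0 * math.pi * vdw_radius(e) ** 3 for e in mol.elements))


def _centered_extent(mol: Molecule) -> float:
    """Maximum axis-aligned span of the solute in Å."""
    span = mol.coordinates.max(axis=0) - mol.coordinates.min(axis=0)
    return float(span.max())


def _random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """n uniform random rotation matrices from normalized quaternions."""
    quat = rng.standard_normal((n, 4))
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    return Rotation.from_quat(quat).as_matrix()


def _random_orientation(template: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    centered = template - template.mean(axis=0)
    return centered @ _random_rotations(1, rng)[0].T


def _insert_molecules(
    occupied: np.ndarray,
    template: np.ndarray,
    count: int,
    box: float,
    cutoff: float,
    rng: np.random.Generator,
    batch: int = 64,
    max_attempts_factor: int = 500,
) -> list[np.ndarray]:
    """Random batch insertion with a k-d tree overlap check.

    A candidate replica is accepted iff every atom stays inside the box
    and no atom comes within ``cutoff`` of any already-present atom.
    """
    placed: list[np.ndarray] = []
    pending = occupied.copy() if len(occupied) else np.empty((0, 3))
    tree = cKDTree(pending) if len(pending) else None
    attempts = 0
    max_attempts = max_attempts_factor * max(count, 1)
    margin = 0.5 * cutoff
    centered = template - template.mean(axis=0)
    n_t = len(centered)
    reach = margin + np.linalg.norm(centered, axis=1).max()
    lo, hi = reach, box - reach
    if hi <= lo:
        raise PackingError("solvent template does not fit in the box")
    while len(placed) < count and attempts < max_attempts:
        n_cand = min(batch, max_attempts - attempts)
        attempts += n_cand
        rots = _random_rotations(n_cand, rng)
        centers = rng.uniform(lo, hi, size=(n_cand, 3))
        cands = np.einsum("ti,cij->ctj", centered, rots) + centers[:, None, :]
        # batched tree query against everything already present
        if tree is not None:
            dmin = tree.query(cands.reshape(-1, 3), k=1)[0].reshape(n_cand, n_t).min(axis=1)
            ok = np.flatnonzero(dmin >= cutoff)
        else:
            ok = np.arange(n_cand)
        fresh: list[np.ndarray] = []
        for idx in ok:
            if len(placed) >= count:
                break
            candidate = cands[idx]
            # brute-force check against molecules accepted within this batch
            # (the tree is rebuilt only once per batch)
            clash = any(
                np.linalg.norm(candidate[:, None, :] - f[None, :, :], axis=-1).min()
                < cutoff
                for f in fresh
            )
            if not clash:
                fresh.append(candidate)
                placed.append(candidate)
        if fresh:
            pending = np.vstack([pending] + fresh)
            tree = cKDTree(pending)
    return placed


def solvate(
    solute: Molecule,
    solvent: SolventSpec | None = None,
    padding_nm: float = DEFAULT_PADDING_NM,
    seed: int = 0,
    cutoff: float = DEFAULT_OVERLAP_CUTOFF,
) -> SolvatedSystem:
    """Pack solvent around the solute in a cubic box.

    The box edge is the solute's largest axis-aligned extent plus twice
    the padding (default 1.0 nm). The target replica count follows from
    the solvent density applied to the accessible volume (box volume
    minus the solute's summed vdW-sphere volume). Raises
    :class:`PackingError` when fewer than 90% of the target can be
    placed.
    """
    if padding_nm <= 0:
        raise ValueError("padding must be positive")
    solvent = solvent or SolventSpec.water()
    rng = np.random.default_rng(seed)

    centered = solute.copy()
    box = _centered_extent(solute) + 2.0 * padding_nm * 10.0
    centered.coordinates = (
        solute.coordinates
        - 0.5 * (solute.coordinates.max(axis=0) + solute.coordinates.min(axis=0))
        + box / 2.0
    )

    accessible = box**3 - solute_volume(solute)
    # molecules per Å^3 = density[g/cm^3] / (mass[amu] * 1.66054)
    target = int(accessible * solvent.density / (solvent.molecular_mass * 1.66054))
    placed = _insert_molecules(
        centered.coordinates,
        solvent.template.coordinates,
        target,
        box,
        cutoff,
        rng,
    )
    if target and len(placed) < 0.9 * target:
        raise PackingError(
            f"placed {len(placed)} of {target} solvent molecules "
            f"(box {box:.1f} Å, cutoff {cutoff} Å); reduce density or cutoff"
        )
    return SolvatedSystem(
        centered,
        solvent.template,
        placed,
        box_edge=box,
        solvent_name=solvent.name,
    )


def custom_solvate(
    solute: Molecule,
    components: list[tuple[Molecule, int]],
    padding_nm: float = DEFAULT_PADDING_NM,
    seed: int = 0,
    cutoff: float = DEFAULT_OVERLAP_CUTOFF,
) -> list[SolvatedSystem]:
    """Insert exact requested counts of each component (mixed solvents).

    Returns one :class:`SolvatedSystem` per component sharing the same
    box and an overlap-consistent joint configuration; an error reports
    achieved counts when a request cannot be met.
    """
    if any(c < 0 for _, c in components):
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    box = _centered_extent(solute) + 2.0 * padding_nm * 10.0
    centered = solute.copy()
    centered.coordinates = (
        solute.coordinates
        - 0.5 * (solute.coordinates.max(axis=0) + solute.coordinates.min(axis=0))
        + box / 2.0
    )
    occupied = centered.coordinates
    systems: list[SolvatedSystem] = []
    for template, count in components:
        placed = _insert_molecules(occupied, template.coordinates, count, box, cutoff, rng)
        if len(placed) < count:
            raise PackingError(
                f"requested {count} copies of a component, placed {len(placed)}"
            )
        if placed:
            occupied = np.vstack([occupied] + placed)
        systems.append(
            SolvatedSystem(centered, template, placed, box_edge=box,
                           solvent_name=template.comment or "SOL")
        )
    return systems


def neutralize(
    system: SolvatedSystem,
    solute_charge: int | None = None,
    seed: int = 0,
    cutoff: float = DEFAULT_OVERLAP_CUTOFF,
) -> SolvatedSystem:
    """Add counterions until the net charge is zero.

    Negative solutes get Na+, positive ones Cl-; placements are random
    and overlap-checked like solvent insertions.
    """
    q = system.solute.formal_charge if solute_charge is None else solute_charge
    if q != int(q):
        raise ValueError("solute charge must be integral")
    q = int(q)
    if q == 0:
        return system
    species = "Na+" if q < 0 else "Cl-"
    rng = np.random.default_rng(seed)
    occupied = system.all_coordinates()
    template = np.zeros((1, 3))
    placed = _insert_molecules(
        occupied, template, abs(q), system.box_edge, cutoff, rng
    )
    if len(placed) < abs(q):
        raise PackingError(f"no room for {abs(q)} {species} counterions")
    system.ions.extend((species, p.reshape(3)) for p in placed)
    return system


def galvani_correct(dg: float, q: int, water_model: str = "SPC/E") -> float:
    """Apply the Galvani surface-potential correction -q*phi_G to dG (kJ/mol)."""
    if water_model not in GALVANI_POTENTIALS:
        raise KeyError(
            f"unknown water model '{water_model}'; registry: {sorted(GALVANI_POTENTIALS)}"
        )
    return dg - q * GALVANI_POTENTIALS[water_model]


# ---------------------------------------------------------------------------
# Writers


def _iter_residues(system: SolvatedSystem):
    yield "LIG", system.solute.elements, system.solute.coordinates
    for pos in system.solvent_positions:
        yield "SOL", system.solvent_template.elements, pos
    for species, p in system.ions:
        yield species.strip("+-").upper(), [_ION_SPECIES[species][0]], p.reshape(1, 3)


def write_gro(system: SolvatedSystem, path) -> None:
    """GROMACS .gro coordinates (nm) with contiguous residue numbering."""
    lines = [f"ffcraft solvated system", f"{system.n_atoms:5d}"]
    atom_no = 0
    for res_no, (res, elements, coords) in enumerate(_iter_residues(system), start=1):
        for e, (x, y, z) in zip(elements, coords):
            atom_no += 1
            lines.append(
                f"{res_no % 100000:5d}{res:<5s}{e:>5s}{atom_no % 100000:5d}"
                f"{x / 10:8.3f}{y / 10:8.3f}{z / 10:8.3f}"
            )
    L = system.box_edge / 10.0
    lines.append(f"{L:10.5f}{L:10.5f}{L:10.5f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_pdb(system: SolvatedSystem, path) -> None:
    """PDB coordinates (Å) with CRYST1 box record."""
    L = system.box_edge
    lines = [f"CRYST1{L:9.3f}{L:9.3f}{L:9.3f}  90.00  90.00  90.00 P 1           1"]
    atom_no = 0
    for res_no, (res, elements, coords) in enumerate(_iter_residues(system), start=1):
        for e, (x, y, z) in zip(elements, coords):
            atom_no += 1
            lines.append(
                f"HETATM{atom_no % 100000:5d} {e:<4s}{res:<4s}{res_no % 10000:5d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {e:>2s}"
            )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_top_counts(system: SolvatedSystem, path) -> None:
    """Minimal GROMACS .top molecule-counts section."""
    counts = [("LIG", 1)]
    if system.n_solvent:
        counts.append(("SOL", system.n_solvent))
    ion_counts: dict[str, int] = {}
    for species, _ in system.ions:
        ion_counts[species] = ion_counts.get(species, 0) + 1
    counts.extend(sorted(ion_counts.items()))
    with open(path, "w") as fh:
        fh.write("[ system ]\nffcraft solvated system\n\n[ molecules ]\n")
        for name, n in counts:
            fh.write(f"{name.strip('+-'):<8s} {n}\n")


def write_system(system: SolvatedSystem, path, fmt: str = "gro") -> None:
    if fmt == "gro":
        write_gro(system, path)
    elif fmt == "pdb":
        write_pdb(system, path)
    elif fmt == "top":
        write_top_counts(system, path)
    else:
        raise ValueError(f"unknown format '{fmt}' (gro|pdb|top)")


def read_gro(path):
    """Re-read a .gro file written here: (elements, coordinates Å, box edge Å)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = int(lines[1])
    elements, coords = [], []
    for line in lines[2 : 2 + n]:
        elements.append(line[10:15].strip())
        coords.append([float(line[20:28]) * 10, float(line[28:36]) * 10, float(line[36:44]) * 10])
    box = float(lines[2 + n].split()[0]) * 10
    return elements, np.array(coords), box


def min_cross_molecule_distance(system: SolvatedSystem) -> float:
    """Brute-force minimum distance between atoms of different molecules."""
    groups = [coords for _, _, coords in _iter_residues(system)]
    best = math.inf
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            d = np.linalg.norm(groups[i][:, None, :] - groups[j][None, :, :], axis=-1)
            best = min(best, float(d.min()))
    return best
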