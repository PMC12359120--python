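"""Conformer generation by exhaustive dihedral enumeration or
high-temperature sampling, with MM minimization, deduplication and
Boltzmann populations.

Enumeration takes the Cartesian product of the torsional minima of every
rotatable bond (minima read off the dominant cosine term of the force
field, falling back to the bond's multiplicity), applies each assignment
with rigid rotations, minimizes on the MM energy (optionally with a
generalized-Born implicit-solvent term) and removes duplicates by joint
energy and best-fit heavy-atom RMSD comparison. The sampling route runs
Langevin dynamics at high temperature (700 K by default, to cross
torsion barriers), minimizes equally spaced snapshots and deduplicates
the same way.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .chem_core import Molecule, RotatableBond, set_dihedral_in_degrees
from .data import KB_KJMOL
from .dynamics import langevin
from . import geometry as geom
from .mm_forcefield import ForceField, evaluate, gb_obc2_energy

DEFAULT_ENERGY_TOL = 0.1  # kJ/mol
DEFAULT_RMSD_TOL = 0.2  # Å
DEFAULT_SAMPLING_TEMPERATURE = 700.0  # K
ENUMERATION_CAP = 10**6


@dataclass
class ConformerEnsemble:
    """Conformers with relative energies, ascending; min energy is 0."""

    conformers: list[tuple[Molecule, float]] = field(default_factory=list)
    provenance: str = "enumerated"

    def __post_init__(self) -> None:
        self._normalize()

    def _normalize(self) -> None:
        self.conformers.sort(key=lambda t: t[1])
        if self.conformers:
            e0 = self.conformers[0][1]
            self.conformers = [(m, e - e0) for m, e in self.conformers]

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def energies(self) -> np.ndarray:
        return np.array([e for _, e in self.conformers])

    def write_xyz(self, path) -> None:
        from .chem_core import write_xyz

        with open(path, "w") as fh:
            for rank, (m, e) in enumerate(self.conformers):
                fh.write(write_xyz(m, f"conformer {rank}  E = {e:.6f} kJ/mol"))


class _ImplicitSolvent:
    """OBC2 generalized-Born water term added to the gas-phase MM energy."""

    def __init__(self, dielectric: float = 78.5):
        self.name = "OBC2"
        self.dielectric = dielectric

    def energy(self, mol: Molecule, ff: ForceField) -> float:
        return gb_obc2_energy(mol, ff.charges, dielectric=self.dielectric)


def show_available_implicit_solvent_models() -> dict:
    """Registry of implicit-solvent models (dielectric is resettable)."""
    return {"OBC2": _ImplicitSolvent()}


# ---------------------------------------------------------------------------
# Enumeration


def _bond_minima(bond: RotatableBond, ff: ForceField | None) -> list[float]:
    """Torsion-minimum angles (deg) for one rotatable bond.

    Uses the force field's dominant (largest |A|) cosine term on the
    bond's reference quadruple: minima of A[1 + cos(p phi - phi0)] at
    phi = (phi0 + (2k+1) pi)/p. Without such a term, ``multiplicity``
    evenly spaced values starting from 180 deg are used.
    """
    terms = ff.terms_on_quad(bond.reference_dihedral) if ff is not None else []
    terms = [t for t in terms if t.A != 0.0]
    if terms:
        t = max(terms, key=lambda t: abs(t.A))
        if t.A > 0:
            angles = [(t.phi0 + (2 * k + 1) * math.pi) / t.p for k in range(t.p)]
        else:  # negative amplitude: maxima of the cosine are the minima
            angles = [(t.phi0 + 2 * k * math.pi) / t.p for k in range(t.p)]
        return [math.degrees(geom.wrap_angle(a)) for a in angles]
    m = bond.multiplicity
    return [math.degrees(geom.wrap_angle(math.radians(180.0 + k * 360.0 / m))) for k in range(m)]


def enumerate_assignments(
    bonds: Sequence[RotatableBond],
    ff: ForceField | None = None,
    cap: int = ENUMERATION_CAP,
) -> list[tuple[float, ...]]:
    """Cartesian product of per-bond minimum angles; count = prod(multiplicities)."""
    total = 1
    for b in bonds:
        total *= len(_bond_minima(b, ff))
    if total > cap:
        raise ValueError(
            f"{total} dihedral assignments exceed the cap of {cap}; "
            "use MD-based conformational_sampling instead"
        )
    assignments: list[tuple[float, ...]] = [()]
    for b in bonds:
        minima = _bond_minima(b, ff)
        assignments = [a + (v,) for a in assignments for v in minima]
    return assignments


# ---------------------------------------------------------------------------
# Minimization


def _minimize_mm(
    mol: Molecule,
    ff: ForceField,
    implicit_solvent: _ImplicitSolvent | None = None,
    gtol: float = 0.5,
    max_steps: int = 2000,
    gb_fd_step: float = 1e-4,
):
    """L-BFGS minimization; returns (coords, energy, converged flag).

    The MM gradient is analytic; the generalized-Born term, when present,
    contributes by central finite differences.
    """
    work = mol.copy()
    n = mol.natoms

    def objective(flat):
        work.coordinates = flat.reshape(n, 3)
        comp, grad = evaluate(work, ff)
        e = comp["total"]
        g = grad.reshape(-1).copy()
        if implicit_solvent is not None:
            e_gb = implicit_solvent.energy(work, ff)
            e += e_gb
            for t in range(3 * n):
                xp = flat.copy()
                xm = flat.copy()
                xp[t] += gb_fd_step
                xm[t] -= gb_fd_step
                work.coordinates = xp.reshape(n, 3)
                ep = implicit_solvent.energy(work, ff)
                work.coordinates = xm.reshape(n, 3)
                em = implicit_solvent.energy(work, ff)
                g[t] += (ep - em) / (2 * gb_fd_step)
        return e, g

    res = minimize(
        objective,
        mol.coordinates.reshape(-1),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_steps, "gtol": 1e-10, "ftol": 1e-14},
    )
    x = res.x.reshape(n, 3)
    e, g = objective(res.x)
    return x, float(e), bool(np.abs(g).max() <= gtol)


def generate_conformers(
    mol: Molecule,
    ff: ForceField,
    implicit_solvent: _ImplicitSolvent | None = None,
    bonds: Sequence[RotatableBond] | None = None,
    energy_tol: float = DEFAULT_ENERGY_TOL,
    rmsd_tol: float = DEFAULT_RMSD_TOL,
) -> ConformerEnsemble:
    """Enumerate dihedral-minimum combinations, minimize each, deduplicate."""
    from .chem_core import detect_rotatable_bonds

    if bonds is None:
        bonds = detect_rotatable_bonds(mol)
    assignments = enumerate_assignments(bonds, ff)
    out: list[tuple[Molecule, float]] = []
    dropped = 0
    for values in assignments:
        work = mol.copy()
        for b, v in zip(bonds, values):
            set_dihedral_in_degrees(work, b.reference_dihedral, v)
        x, e, converged = _minimize_mm(work, ff, implicit_solvent)
        if not converged:
            dropped += 1
            warnings.warn(f"minimization did not converge for assignment {values}; dropped")
            continue
        work.coordinates = x
        out.append((work, e))
    ens = ConformerEnsemble(out, provenance="enumerated")
    return deduplicate(ens, energy_tol, rmsd_tol)


# ---------------------------------------------------------------------------
# Deduplication / populations


def _heavy_rmsd(a: Molecule, b: Molecule) -> float:
    heavy = [i for i, e in enumerate(a.elements) if e != "H"]
    if not heavy:
        heavy = list(range(a.natoms))
    return geom.kabsch_rmsd(a.coordinates[heavy], b.coordinates[heavy])


def deduplicate(
    ensemble: ConformerEnsemble,
    energy_tol: float = DEFAULT_ENERGY_TOL,
    rmsd_tol: float = DEFAULT_RMSD_TOL,
) -> ConformerEnsemble:
    """Greedy ascending-energy pass: duplicates match in energy AND structure.

    Two conformers are the same iff |dE| <= energy_tol and heavy-atom
    best-fit RMSD <= rmsd_tol; the lower-energy representative is kept.
    Molecular-symmetry automorphisms are not considered, so symmetric
    conformers may be counted separately.
    """
    if energy_tol <= 0 or rmsd_tol <= 0:
        raise ValueError("tolerances must be positive")
    survivors: list[tuple[Molecule, float]] = []
    for mol, e in ensemble.conformers:  # already sorted ascending
        dup = any(
            abs(e - e_s) <= energy_tol and _heavy_rmsd(mol, m_s) <= rmsd_tol
            for m_s, e_s in survivors
        )
        if not dup:
            survivors.append((mol, e))
    return ConformerEnsemble(survivors, provenance=ensemble.provenance)


def calculate_boltzmann_distribution(energies, temperature: float = 298.15) -> np.ndarray:
    """Equilibrium populations p_i ∝ exp(-(E_i - E_min)/kT); sums to 1."""
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValueError("no energies given")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    w = np.exp(-(e - e.min()) / (KB_KJMOL * temperature))
    return w / w.sum()


# ---------------------------------------------------------------------------
# MD-based sampling


def conformational_sampling(
    mol: Molecule,
    ff: ForceField,
    n_snapshots: int = 50,
    duration_ps: float = 10.0,
    temperature: float = DEFAULT_SAMPLING_TEMPERATURE,
    timestep_fs: float = 0.5,
    seed: int = 0,
    energy_tol: float = DEFAULT_ENERGY_TOL,
    rmsd_tol: float = DEFAULT_RMSD_TOL,
) -> ConformerEnsemble:
    """High-temperature Langevin sampling; snapshots minimized and deduplicated.

    The default 700 K lets the trajectory cross torsional barriers that
    are inaccessible at room temperature.
    """
    n_steps = max(int(round(duration_ps * 1000.0 / timestep_fs)), n_snapshots)
    every = max(n_steps // n_snapshots, 1)
    snapshots: list[np.ndarray] = []

    def force(x):
        work.coordinates = x
        return -evaluate(work, ff)[1]

    work = mol.copy()

    def monitor(step, x):
        if (step + 1) % every == 0 and len(snapshots) < n_snapshots:
            snapshots.append(x.copy())
        return None

    langevin(
        mol.coordinates,
        mol.masses,
        force,
        n_steps=n_steps,
        timestep_fs=timestep_fs,
        temperature=temperature,
        rng=np.random.default_rng(seed),
        callback=monitor,
    )
    out: list[tuple[Molecule, float]] = []
    for x in snapshots:
        snap = mol.copy()
        snap.coordinates = x
        xmin, e, converged = _minimize_mm(snap, ff)
        if not converged:
            warnings.warn("snapshot minimization did not converge; dropped")
            continue
        snap.coordinates = xmin
        out.append((snap, e))
    ens = ConformerEnsemble(out, provenance="sampled")
    return deduplicate(ens, energy_tol, rmsd_tol)
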