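"""Molecular-mechanics force field: data model, energy and analytic
gradient, Seminario Hessian-derived constants, GROMACS topology export
and a generalized-Born (OBC-II) implicit-solvent term.

The potential is the classical fixed-charge form

    V = sum_bonds  1/2 k (r - r0)^2
      + sum_angles 1/2 k (theta - theta0)^2
      + sum_torsions sum_i A_i [1 + cos(p_i phi - phi0_i)]
      + sum_pairs 4 eps [(sigma/r)^12 - (sigma/r)^6] + ke q_a q_b / r

with 1-2 and 1-3 nonbonded pairs excluded and 1-4 pairs scaled
(AMBER convention: Coulomb 1/1.2, LJ 1/2 by default). Internal units
are Å, kJ/mol, radians and elementary charges; GROMACS units appear
only in the writer/reader.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .chem_core import Molecule, angles_from_bonds, canonical_bond
from .data import COULOMB_KE, atomic_mass
from . import geometry as geom


@dataclass
class DihedralTerm:
    """One cosine term A[1 + cos(p*phi - phi0)] on a torsion quadruple.

    A is the barrier height in kJ/mol (may be negative during fitting),
    p the integer periodicity >= 1 and phi0 the phase in radians. A
    quadruple may carry several terms with distinct (p, phi0).
    """

    quad: tuple[int, int, int, int]
    A: float
    p: int
    phi0: float

    def __post_init__(self) -> None:
        self.quad = tuple(int(i) for i in self.quad)  # type: ignore[assignment]
        if self.p < 1:
            raise ValueError(f"periodicity must be >= 1, got {self.p}")
        if not math.isfinite(self.A):
            raise ValueError("non-finite barrier height")


@dataclass
class FitReport:
    rmse: float
    max_deviation: float
    n_points: int
    amplitudes: dict


@dataclass
class ForceField:
    """Per-atom nonbonded parameters plus bonded terms.

    bond and angle force constants follow the harmonic convention
    E = 1/2 k dx^2 (GROMACS-style); sigma in Å, epsilon in kJ/mol.
    """

    charges: np.ndarray  # e
    sigmas: np.ndarray  # Å
    epsilons: np.ndarray  # kJ/mol
    atom_types: list[str]
    bond_terms: dict = field(default_factory=dict)  # (a,b) -> (k kJ/mol/Å^2, r0 Å)
    angle_terms: dict = field(default_factory=dict)  # (a,b,c) -> (k kJ/mol/rad^2, th0 rad)
    dihedral_terms: list[DihedralTerm] = field(default_factory=list)
    coulomb_14_scale: float = 1.0 / 1.2
    lj_14_scale: float = 0.5
    last_fit_report: FitReport | None = None

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.epsilons = np.asarray(self.epsilons, dtype=float)
        if np.any(self.sigmas <= 0):
            raise ValueError("LJ sigma must be positive")
        if np.any(self.epsilons < 0):
            raise ValueError("LJ epsilon must be non-negative")

    @property
    def natoms(self) -> int:
        return len(self.charges)

    def copy(self) -> "ForceField":
        return ForceField(
            self.charges.copy(),
            self.sigmas.copy(),
            self.epsilons.copy(),
            list(self.atom_types),
            dict(self.bond_terms),
            dict(self.angle_terms),
            [DihedralTerm(t.quad, t.A, t.p, t.phi0) for t in self.dihedral_terms],
            self.coulomb_14_scale,
            self.lj_14_scale,
        )

    def terms_on_quad(self, quad: Sequence[int]) -> list[DihedralTerm]:
        quad = tuple(quad)
        rev = quad[::-1]
        return [t for t in self.dihedral_terms if t.quad == quad or t.quad == rev]


def blank_forcefield(
    mol: Molecule,
    sigma: float = 3.4,
    epsilon: float = 0.36,
    bond_k: float = 2000.0,
    angle_k: float = 400.0,
) -> ForceField:
    """Zero-charge force field with equilibrium values taken from the geometry.

    Convenient for rigid-scan fitting and toy systems where the bonded
    terms only need to hold the frame together.
    """
    n = mol.natoms
    ff = ForceField(
        charges=np.zeros(n),
        sigmas=np.full(n, sigma),
        epsilons=np.full(n, epsilon),
        atom_types=[f"{e}{i}" for i, e in enumerate(mol.elements)],
    )
    x = mol.coordinates
    for a, b in sorted(mol.bonds):
        ff.bond_terms[(a, b)] = (bond_k, geom.bond_value(x, a, b))
    for a, b, c in angles_from_bonds(mol):
        ff.angle_terms[(a, b, c)] = (angle_k, geom.angle_value(x, a, b, c))
    return ff


# ---------------------------------------------------------------------------
# Energy / gradient


def torsion_energy(phi, terms: Sequence[DihedralTerm]):
    """Cosine-series torsion potential evaluated at angle(s) phi (radians)."""
    phi = np.asarray(phi, dtype=float)
    e = np.zeros_like(phi)
    for t in terms:
        e = e + t.A * (1.0 + np.cos(t.p * phi - t.phi0))
    return float(e) if e.shape == () else e


_PAIR_CACHE: dict = {}


def _nonbonded_pairs(mol: Molecule):
    """(full pairs, 1-4 pairs) from bond-graph distances: 1-2/1-3 excluded.

    Cached on the bond topology, which dynamics and minimization never change.
    """
    key = (mol.natoms, frozenset(mol.bonds))
    hit = _PAIR_CACHE.get(key)
    if hit is not None:
        return hit
    g = mol.graph()
    n = mol.natoms
    dist = dict(nx.all_pairs_shortest_path_length(g, cutoff=3))
    full, one4 = [], []
    for a in range(n):
        da = dist.get(a, {})
        for b in range(a + 1, n):
            d = da.get(b)
            if d is None:
                full.append((a, b))
            elif d == 3:
                one4.append((a, b))
            # d in (1, 2) -> excluded
    result = (np.array(full, dtype=int).reshape(-1, 2), np.array(one4, dtype=int).reshape(-1, 2))
    if len(_PAIR_CACHE) > 64:
        _PAIR_CACHE.clear()
    _PAIR_CACHE[key] = result
    return result


def evaluate(mol: Molecule, ff: ForceField):
    """Energy components (kJ/mol) and analytic Cartesian gradient (kJ/mol/Å).

    Every bond and angle implied by the molecule's bond graph must carry a
    parameter; a missing term raises KeyError naming it.
    """
    x = mol.coordinates
    n = mol.natoms
    grad = np.zeros((n, 3))
    comp = {"bond": 0.0, "angle": 0.0, "dihedral": 0.0, "lj": 0.0, "coulomb": 0.0}

    for a, b in sorted(mol.bonds):
        key = canonical_bond(a, b)
        if key not in ff.bond_terms:
            raise KeyError(f"missing bond parameter for atoms {key}")
        k, r0 = ff.bond_terms[key]
        r, dg = geom.bond_grad(x, a, b)
        comp["bond"] += 0.5 * k * (r - r0) ** 2
        for idx, g in dg.items():
            grad[idx] += k * (r - r0) * g

    for a, b, c in angles_from_bonds(mol):
        key = (a, b, c) if (a, b, c) in ff.angle_terms else (c, b, a)
        if key not in ff.angle_terms:
            raise KeyError(f"missing angle parameter for atoms {(a, b, c)}")
        k, th0 = ff.angle_terms[key]
        th, dg = geom.angle_grad(x, a, b, c)
        comp["angle"] += 0.5 * k * (th - th0) ** 2
        for idx, g in dg.items():
            grad[idx] += k * (th - th0) * g

    for t in ff.dihedral_terms:
        i, j, k_, l = t.quad
        phi, dg = geom.dihedral_grad(x, i, j, k_, l)
        comp["dihedral"] += t.A * (1.0 + math.cos(t.p * phi - t.phi0))
        dEdphi = -t.A * t.p * math.sin(t.p * phi - t.phi0)
        for idx, g in dg.items():
            grad[idx] += dEdphi * g

    full, one4 = _nonbonded_pairs(mol)
    for pairs, cscale, ljscale in ((full, 1.0, 1.0), (one4, ff.coulomb_14_scale, ff.lj_14_scale)):
        if len(pairs) == 0:
            continue
        ai, bi = pairs[:, 0], pairs[:, 1]
        rvec = x[ai] - x[bi]
        r = np.linalg.norm(rvec, axis=1)
        sig = 0.5 * (ff.sigmas[ai] + ff.sigmas[bi])
        eps = np.sqrt(ff.epsilons[ai] * ff.epsilons[bi])
        sr6 = (sig / r) ** 6
        elj = 4.0 * eps * (sr6 * sr6 - sr6) * ljscale
        dlj = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r * ljscale
        ec = COULOMB_KE * ff.charges[ai] * ff.charges[bi] / r * cscale
        dc = -ec / r
        comp["lj"] += float(elj.sum())
        comp["coulomb"] += float(ec.sum())
        pair_grad = ((dlj + dc) / r)[:, None] * rvec
        np.add.at(grad, ai, pair_grad)
        np.add.at(grad, bi, -pair_grad)

    comp["total"] = sum(v for k, v in comp.items() if k != "total")
    return comp, grad


def energy(mol: Molecule, ff: ForceField) -> float:
    return evaluate(mol, ff)[0]["total"]


# ---------------------------------------------------------------------------
# Seminario method


def _seminario_eigen(hessian: np.ndarray, a: int, b: int):
    """Eigenvalues/vectors of the negated 3x3 interatomic Hessian block."""
    block = -hessian[3 * a : 3 * a + 3, 3 * b : 3 * b + 3]
    w, v = np.linalg.eig(block)
    return np.real(w), np.real(v)


def seminario_parameters(mol: Molecule, hessian: np.ndarray):
    """Harmonic bond/angle constants from a Cartesian Hessian (Seminario 1996).

    The bond constant for a-b is sum_m lambda_m |u_ab . v_m| over the
    eigenpairs of the negated interatomic block -H[a,b]; the angle
    constant combines the projections of the two bond blocks onto the
    in-plane perpendicular unit vectors. Equilibrium values come from
    the input geometry. Negative constants are clamped to zero.
    """
    n = mol.natoms
    hessian = np.asarray(hessian, dtype=float)
    if hessian.shape != (3 * n, 3 * n):
        raise ValueError(f"Hessian must be {3*n}x{3*n}")
    if not np.allclose(hessian, hessian.T, atol=1e-8 * max(1.0, np.abs(hessian).max())):
        raise ValueError("Hessian is not symmetric")
    x = mol.coordinates

    def _projected_sum(a: int, b: int, direction: np.ndarray) -> float:
        w, v = _seminario_eigen(hessian, a, b)
        return float(sum(w[m] * abs(np.dot(direction, v[:, m])) for m in range(3)))

    bond_params = {}
    for a, b in sorted(mol.bonds):
        u = x[a] - x[b]
        r = np.linalg.norm(u)
        u = u / r
        k = _projected_sum(a, b, u)
        bond_params[(a, b)] = (max(k, 0.0), float(r))

    angle_params = {}
    for a, b, c in angles_from_bonds(mol):
        u_ab = x[a] - x[b]
        u_cb = x[c] - x[b]
        r_ab = np.linalg.norm(u_ab)
        r_cb = np.linalg.norm(u_cb)
        u_ab = u_ab / r_ab
        u_cb = u_cb / r_cb
        u_n = np.cross(u_cb, u_ab)
        u_n = u_n / np.linalg.norm(u_n)
        u_pa = np.cross(u_n, u_ab)
        u_pc = np.cross(u_cb, u_n)
        ka = _projected_sum(a, b, u_pa)
        kc = _projected_sum(c, b, u_pc)
        # The perpendicular projections of the two terminal-atom blocks carry
        # a geometric 1-3 coupling: an isolated harmonic angle k yields
        # R_ab^2 sum = k (1 - cos(theta) R_ab/R_cb) and symmetrically for the
        # other bond. Rescaling the harmonic combination by that factor makes
        # the isolated-angle Hessian invert exactly.
        cos_t = float(np.dot(u_ab, u_cb))
        corr = 1.0 / (1.0 - cos_t * r_ab / r_cb) + 1.0 / (1.0 - cos_t * r_cb / r_ab)
        if ka > 0 and kc > 0:
            k_theta = corr / (1.0 / (r_ab**2 * ka) + 1.0 / (r_cb**2 * kc))
        else:
            k_theta = 0.0
        angle_params[(a, b, c)] = (max(k_theta, 0.0), geom.angle_value(x, a, b, c))

    return bond_params, angle_params


# ---------------------------------------------------------------------------
# Generalized Born (OBC-II)


GB_OFFSET = 0.09  # Å, intrinsic-radius offset
GB_ALPHA, GB_BETA, GB_GAMMA = 1.0, 0.8, 4.85


def _obc2_effective_radii(x: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """OBC-II effective Born radii from intrinsic (offset) radii in Å."""
    n = len(x)
    eff = np.empty(n)
    for i in range(n):
        rho_i = radii[i]
        integral = 0.0
        for j in range(n):
            if j == i:
                continue
            r = np.linalg.norm(x[i] - x[j])
            s_j = radii[j]
            if rho_i >= r + s_j:
                continue  # j fully inside i
            upper = r + s_j
            lower = max(abs(r - s_j), rho_i)
            integral += 0.5 * (
                1.0 / lower
                - 1.0 / upper
                + 0.25 * (r - s_j**2 / r) * (1.0 / upper**2 - 1.0 / lower**2)
                + 0.5 / r * math.log(lower / upper)
            )
        psi = integral * rho_i
        inv = 1.0 / rho_i - math.tanh(
            GB_ALPHA * psi - GB_BETA * psi**2 + GB_GAMMA * psi**3
        ) / (rho_i + GB_OFFSET)
        eff[i] = 1.0 / inv
    return eff


def gb_obc2_energy(
    mol: Molecule,
    charges: np.ndarray | None = None,
    radii: np.ndarray | None = None,
    dielectric: float = 78.5,
) -> float:
    """Polar solvation energy (kJ/mol) from the OBC-II generalized-Born model.

    ``radii`` are intrinsic Born radii in Å (van der Waals radii minus
    the standard 0.09 Å offset when not supplied). For a single ion the
    expression reduces to the Born self-energy -(1 - 1/eps) ke q^2 / 2R.
    """
    if dielectric <= 0:
        raise ValueError("dielectric must be positive")
    x = mol.coordinates
    q = np.zeros(mol.natoms) if charges is None else np.asarray(charges, dtype=float)
    if radii is None:
        from .data import vdw_radius

        radii = np.array([vdw_radius(e) - GB_OFFSET for e in mol.elements])
    else:
        radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("Born radii must be positive")
    if not np.any(q):
        return 0.0
    b = _obc2_effective_radii(x, radii)
    pref = -0.5 * COULOMB_KE * (1.0 - 1.0 / dielectric)
    e = 0.0
    for i in range(mol.natoms):
        for j in range(mol.natoms):
            if i == j:
                f = b[i]
            else:
                r2 = float(np.sum((x[i] - x[j]) ** 2))
                f = math.sqrt(r2 + b[i] * b[j] * math.exp(-r2 / (4.0 * b[i] * b[j])))
            e += pref * q[i] * q[j] / f
    return e


# ---------------------------------------------------------------------------
# GROMACS export


def write_gromacs(mol: Molecule, ff: ForceField, path_prefix: str) -> tuple[str, str]:
    """Write <prefix>.itp and <prefix>.top (funct 1 bonds/angles, funct 9 dihedrals).

    Charges, sigma (nm), epsilon (kJ/mol) go into the .itp; the .top
    includes it with default AMBER-style fudge factors. Returns the two
    paths written.
    """
    itp_path = f"{path_prefix}.itp"
    top_path = f"{path_prefix}.top"
    name = "MOL"
    lines = [f"; topology written by ffcraft", "", "[ atomtypes ]",
             "; name  at.num  mass  charge  ptype  sigma(nm)  epsilon(kJ/mol)"]
    seen = set()
    for i, t in enumerate(ff.atom_types):
        if t in seen:
            continue
        seen.add(t)
        lines.append(
            f"{t:<8s} 0 {atomic_mass(mol.elements[i]):10.4f} 0.0000  A "
            f"{ff.sigmas[i] * 0.1:12.6e} {ff.epsilons[i]:12.6e}"
        )
    lines += ["", "[ moleculetype ]", "; name  nrexcl", f"{name}  3", "", "[ atoms ]",
              "; nr  type  resnr  residue  atom  cgnr  charge  mass"]
    for i in range(mol.natoms):
        lines.append(
            f"{i + 1:5d} {ff.atom_types[i]:<8s} 1 {name} "
            f"{mol.elements[i]:<4s} {i + 1:5d} {ff.charges[i]:14.8f} "
            f"{atomic_mass(mol.elements[i]):10.4f}"
        )
    lines += ["", "[ bonds ]", ";  ai  aj  funct  r0(nm)  k(kJ/mol/nm^2)"]
    for (a, b), (k, r0) in sorted(ff.bond_terms.items()):
        lines.append(f"{a + 1:5d} {b + 1:5d}  1 {r0 * 0.1:12.6f} {k * 100.0:14.4f}")
    lines += ["", "[ angles ]", ";  ai  aj  ak  funct  theta0(deg)  k(kJ/mol/rad^2)"]
    for (a, b, c), (k, th0) in sorted(ff.angle_terms.items()):
        lines.append(
            f"{a + 1:5d} {b + 1:5d} {c + 1:5d}  1 {math.degrees(th0):12.4f} {k:14.4f}"
        )
    lines += ["", "[ dihedrals ]", ";  ai  aj  ak  al  funct  phase(deg)  k(kJ/mol)  mult"]
    for t in ff.dihedral_terms:
        i, j, k_, l = t.quad
        lines.append(
            f"{i + 1:5d} {j + 1:5d} {k_ + 1:5d} {l + 1:5d}  9 "
            f"{math.degrees(t.phi0):12.4f} {t.A:14.6f} {t.p:3d}"
        )
    full, one4 = _nonbonded_pairs(mol)
    lines += ["", "[ pairs ]", ";  ai  aj  funct"]
    for a, b in one4:
        lines.append(f"{a + 1:5d} {b + 1:5d}  1")
    with open(itp_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    with open(top_path, "w") as fh:
        fh.write(
            "[ defaults ]\n; nbfunc  comb-rule  gen-pairs  fudgeLJ  fudgeQQ\n"
            f"1  2  yes  {ff.lj_14_scale:.4f}  {ff.coulomb_14_scale:.6f}\n\n"
            f'#include "{itp_path}"\n\n'
            f"[ system ]\n{name}\n\n[ molecules ]\n{name}  1\n"
        )
    return itp_path, top_path


def read_gromacs_itp(path: str) -> ForceField:
    """Re-read a topology written by :func:`write_gromacs` (internal round trip)."""
    section = None
    atoms, types = [], {}
    bond_terms, angle_terms, dihedrals = {}, {}, []
    with open(path) as fh:
        for raw in fh:
            line = raw.split(";")[0].strip()
            if not line:
                continue
            if line.startswith("["):
                section = line.strip("[] ").lower()
                continue
            parts = line.split()
            if section == "atomtypes":
                types[parts[0]] = (float(parts[5]) * 10.0, float(parts[6]))  # nm->Å
            elif section == "atoms":
                atoms.append((parts[1], float(parts[6])))
            elif section == "bonds":
                a, b = int(parts[0]) - 1, int(parts[1]) - 1
                bond_terms[(a, b)] = (float(parts[4]) / 100.0, float(parts[3]) * 10.0)
            elif section == "angles":
                a, b, c = (int(p) - 1 for p in parts[:3])
                angle_terms[(a, b, c)] = (float(parts[5]), math.radians(float(parts[4])))
            elif section == "dihedrals":
                i, j, k, l = (int(p) - 1 for p in parts[:4])
                dihedrals.append(
                    DihedralTerm((i, j, k, l), float(parts[6]), int(parts[7]),
                                 math.radians(float(parts[5])))
                )
    charges = np.array([q for _, q in atoms])
    sigmas = np.array([types[t][0] for t, _ in atoms])
    epsilons = np.array([types[t][1] for t, _ in atoms])
    return ForceField(
        charges, sigmas, epsilons, [t for t, _ in atoms],
        bond_terms, angle_terms, dihedrals,
    )
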