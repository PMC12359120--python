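"""Analytic stand-in potentials and fixture molecules.

Every oracle is a callable ``x -> (E, gradient, Hessian)`` in kJ/mol,
kJ/mol/Å and kJ/mol/Å²: the same contract the interpolation builder
expects from an electronic-structure backend, but cheap, deterministic
and with derivatives that agree with finite differences by
construction. Fixture molecules (water, ethane, butane, a biphenyl,
hydrogen peroxide) are generated from internal coordinates at run time,
so no structure files ship with the package.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .chem_core import Molecule, perceive_bonds
from .dihedral_refit import DihedralScan
from . import geometry as geom


# ---------------------------------------------------------------------------
# Oracles


class HarmonicOracle:
    """Pure Cartesian quadratic: E = 1/2 (x-x0)^T H0 (x-x0)."""

    def __init__(self, x0: np.ndarray, h0: np.ndarray):
        self.x0 = np.asarray(x0, dtype=float)
        h0 = np.asarray(h0, dtype=float)
        if not np.allclose(h0, h0.T, atol=1e-10):
            raise ValueError("reference Hessian must be symmetric")
        self.h0 = h0

    def energy_gradient(self, x: np.ndarray):
        dx = (np.asarray(x, dtype=float) - self.x0).reshape(-1)
        g = self.h0 @ dx
        return float(0.5 * dx @ g), g.reshape(-1, 3)

    def __call__(self, x: np.ndarray):
        e, g = self.energy_gradient(x)
        return e, g, self.h0.copy()


def harmonic_oracle(x0: np.ndarray, h0: np.ndarray) -> HarmonicOracle:
    return HarmonicOracle(x0, h0)


class TorsionOracle:
    """Stiff harmonic frame plus a cosine torsion series on one dihedral.

    E = sum_bonds 1/2 k (r - r0)^2 + sum_angles 1/2 k (theta - theta0)^2
        + sum_i A_i [1 + cos(p_i phi - phi0_i)].

    The gradient is analytic through the internal-coordinate chain rule;
    the Hessian combines the analytic curvature in each internal
    coordinate with the internal-coordinate second derivatives obtained
    by central differences of the analytic first derivatives.
    """

    def __init__(
        self,
        mol: Molecule,
        torsion_quad: Sequence[int],
        torsion_terms: Sequence[tuple[float, int, float]],  # (A, p, phi0 rad)
        bond_k: float = 3000.0,
        angle_k: float = 500.0,
    ):
        from .chem_core import angles_from_bonds

        if not mol.bonds:
            raise ValueError("oracle template needs a perceived bond graph")
        for _, p, _ in torsion_terms:
            if p < 1:
                raise ValueError("periodicity must be >= 1")
        x = mol.coordinates
        self.natoms = mol.natoms
        self.bonds = [
            ((a, b), bond_k, geom.bond_value(x, a, b)) for a, b in sorted(mol.bonds)
        ]
        self.angles = [
            ((a, b, c), angle_k, geom.angle_value(x, a, b, c))
            for a, b, c in angles_from_bonds(mol)
        ]
        self.quad = tuple(torsion_quad)
        self.terms = [(float(a), int(p), float(f)) for a, p, f in torsion_terms]

    # each internal contributes E(q); _internals yields (value, grad-dict, dE/dq, d2E/dq2)
    def _internals(self, x: np.ndarray):
        for (a, b), k, r0 in self.bonds:
            r, g = geom.bond_grad(x, a, b)
            yield g, k * (r - r0), k, 0.5 * k * (r - r0) ** 2
        for (a, b, c), k, t0 in self.angles:
            t, g = geom.angle_grad(x, a, b, c)
            yield g, k * (t - t0), k, 0.5 * k * (t - t0) ** 2
        phi, g = geom.dihedral_grad(x, *self.quad)
        de = sum(-a * p * math.sin(p * phi - f) for a, p, f in self.terms)
        d2e = sum(-a * p * p * math.cos(p * phi - f) for a, p, f in self.terms)
        e = sum(a * (1.0 + math.cos(p * phi - f)) for a, p, f in self.terms)
        yield g, de, d2e, e

    def energy_gradient(self, x: np.ndarray):
        x = np.asarray(x, dtype=float).reshape(self.natoms, 3)
        e_tot = 0.0
        grad = np.zeros_like(x)
        for gdict, de, _, e in self._internals(x):
            e_tot += e
            for idx, v in gdict.items():
                grad[idx] += de * v
        return float(e_tot), grad

    def __call__(self, x: np.ndarray, fd_step: float = 1e-6):
        x = np.asarray(x, dtype=float).reshape(self.natoms, 3)
        e, grad = self.energy_gradient(x)
        n3 = 3 * self.natoms

        # rows of B and per-internal dE/dq, d2E/dq2 at x
        rows, de_list, d2e_list = [], [], []
        for gdict, de, d2e, _ in self._internals(x):
            row = np.zeros(n3)
            for idx, v in gdict.items():
                row[3 * idx : 3 * idx + 3] = v
            rows.append(row)
            de_list.append(de)
            d2e_list.append(d2e)
        B = np.array(rows)
        hess = (B.T * np.array(d2e_list)) @ B

        # curvature of the internals themselves: d2q/dx2 by FD of analytic rows
        flat = x.reshape(-1)
        for t in range(n3):
            xp, xm = flat.copy(), flat.copy()
            xp[t] += fd_step
            xm[t] -= fd_step
            rows_p, rows_m = [], []
            for gdict, *_ in self._internals(xp.reshape(-1, 3)):
                row = np.zeros(n3)
                for idx, v in gdict.items():
                    row[3 * idx : 3 * idx + 3] = v
                rows_p.append(row)
            for gdict, *_ in self._internals(xm.reshape(-1, 3)):
                row = np.zeros(n3)
                for idx, v in gdict.items():
                    row[3 * idx : 3 * idx + 3] = v
                rows_m.append(row)
            dB = (np.array(rows_p) - np.array(rows_m)) / (2 * fd_step)
            hess[:, t] += np.array(de_list) @ dB
        hess = 0.5 * (hess + hess.T)
        return e, grad, hess


def torsion_oracle(
    mol: Molecule,
    torsion_quad: Sequence[int],
    torsion_terms: Sequence[tuple[float, int, float]],
    **kwargs,
) -> TorsionOracle:
    return TorsionOracle(mol, torsion_quad, torsion_terms, **kwargs)


# ---------------------------------------------------------------------------
# Synthetic scans


def synthetic_scan(
    quad: Sequence[int],
    params: Sequence[tuple[float, int, float]],  # (A kJ/mol, p, phi0 rad)
    n_points: int = 19,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DihedralScan:
    """Scan with equidistant angles over 360 deg and cosine-series energies.

    Gaussian noise of standard deviation ``noise_sd`` (kJ/mol) is added
    reproducibly under ``seed``.
    """
    if n_points < 4:
        raise ValueError("need at least 4 scan points")
    angles = -180.0 + np.arange(n_points) * 360.0 / n_points
    phi = np.radians(angles)
    energies = np.zeros(n_points)
    for a, p, f in params:
        energies += a * (1.0 + np.cos(p * phi - f))
    if noise_sd:
        energies = energies + np.random.default_rng(seed).normal(0, noise_sd, n_points)
    return DihedralScan(tuple(quad), angles, energies)


# ---------------------------------------------------------------------------
# Fixture molecules


def _zmat_to_cart(zmat) -> np.ndarray:
    """Natural-extension (NeRF) z-matrix to Cartesian conversion.

    Entries: (el,), (el, a, r), (el, a, r, b, theta_deg),
    (el, a, r, b, theta_deg, c, phi_deg) with 0-based references.
    """
    coords: list[np.ndarray] = []
    for entry in zmat:
        if len(entry) == 1:
            coords.append(np.zeros(3))
        elif len(entry) == 3:
            _, a, r = entry
            coords.append(coords[a] + np.array([r, 0.0, 0.0]))
        elif len(entry) == 5:
            _, a, r, b, theta = entry
            th = math.radians(theta)
            d = coords[a] - coords[b]
            d /= np.linalg.norm(d)
            perp = np.cross(d, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-8:
                perp = np.cross(d, [0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            coords.append(coords[a] + r * (-d * math.cos(th) + perp * math.sin(th)))
        else:
            _, a, r, b, theta, c, phi = entry
            th, ph = math.radians(theta), math.radians(phi)
            bc = coords[a] - coords[b]
            bc /= np.linalg.norm(bc)
            n = np.cross(coords[b] - coords[c], bc)
            n /= np.linalg.norm(n)
            m = np.cross(n, bc)
            d2 = np.array(
                [-r * math.cos(th), r * math.sin(th) * math.cos(ph), r * math.sin(th) * math.sin(ph)]
            )
            coords.append(coords[a] + d2[0] * bc + d2[1] * m + d2[2] * n)
    return np.array(coords)


def _biphenyl() -> Molecule:
    """Two benzene rings joined by a single acyclic C-C bond, 45 deg twist."""
    r_cc, r_ch, r_link = 1.40, 1.08, 1.48
    ring = np.array(
        [
            [r_cc * math.cos(k * math.pi / 3), r_cc * math.sin(k * math.pi / 3), 0.0]
            for k in range(6)
        ]
    )
    elements: list[str] = []
    coords: list[np.ndarray] = []
    # first ring: junction atom at -r_link/2, ring extending toward -x
    ring1 = (ring - ring[0]) + np.array([-r_link / 2.0, 0.0, 0.0])
    for k in range(6):
        elements.append("C")
        coords.append(ring1[k])
    # second ring: flipped to extend toward +x, then twisted about the link axis
    tw = math.radians(45.0)
    flip = np.diag([-1.0, -1.0, 1.0])
    twist = np.array(
        [[1, 0, 0], [0, math.cos(tw), -math.sin(tw)], [0, math.sin(tw), math.cos(tw)]]
    )
    ring2 = ((ring - ring[0]) @ flip.T @ twist.T) + np.array([r_link / 2.0, 0.0, 0.0])
    for k in range(6):
        elements.append("C")
        coords.append(ring2[k])
    # hydrogens on every carbon except the two junction atoms (index 0 of each ring)
    for base, center_shift in ((0, ring1.mean(axis=0)), (6, ring2.mean(axis=0))):
        for k in range(1, 6):
            c = coords[base + k]
            out = c - center_shift
            out /= np.linalg.norm(out)
            elements.append("H")
            coords.append(c + r_ch * out)
    mol = Molecule(elements, np.array(coords))
    return perceive_bonds(mol)


_TETRA = 109.471


def fixture_molecule(name: str) -> Molecule:
    """Small named test molecules with bonds perceived.

    Known names: water, ethane, butane, biphenyl_like, peroxide
    (an H-O-O-H chain, the smallest molecule with a torsion).
    """
    if name == "water":
        z = [("O",), ("H", 0, 0.9572), ("H", 0, 0.9572, 1, 104.52)]
        els = ["O", "H", "H"]
    elif name == "ethane":
        z = [
            ("C",),
            ("C", 0, 1.536),
            ("H", 0, 1.091, 1, 110.9),
            ("H", 0, 1.091, 1, 110.9, 2, 120.0),
            ("H", 0, 1.091, 1, 110.9, 2, -120.0),
            ("H", 1, 1.091, 0, 110.9, 2, 60.0),
            ("H", 1, 1.091, 0, 110.9, 2, 180.0),
            ("H", 1, 1.091, 0, 110.9, 2, -60.0),
        ]
        els = [e[0] for e in z]
    elif name == "butane":
        z = [
            ("C",),
            ("C", 0, 1.531),
            ("C", 1, 1.531, 0, 112.8),
            ("C", 2, 1.531, 1, 112.8, 0, 180.0),
            ("H", 0, 1.092, 1, 110.5, 2, 60.0),
            ("H", 0, 1.092, 1, 110.5, 2, 180.0),
            ("H", 0, 1.092, 1, 110.5, 2, -60.0),
            ("H", 1, 1.094, 2, 109.3, 3, 58.0),
            ("H", 1, 1.094, 2, 109.3, 3, -58.0),
            ("H", 2, 1.094, 1, 109.3, 0, 58.0),
            ("H", 2, 1.094, 1, 109.3, 0, -58.0),
            ("H", 3, 1.092, 2, 110.5, 1, 60.0),
            ("H", 3, 1.092, 2, 110.5, 1, 180.0),
            ("H", 3, 1.092, 2, 110.5, 1, -60.0),
        ]
        els = [e[0] for e in z]
    elif name == "peroxide":
        z = [
            ("H",),
            ("O", 0, 0.965),
            ("O", 1, 1.452, 0, 100.0),
            ("H", 2, 0.965, 1, 100.0, 0, 115.0),
        ]
        els = [e[0] for e in z]
    elif name == "biphenyl_like":
        return _biphenyl()
    else:
        raise ValueError(f"unknown fixture molecule '{name}'")
    mol = Molecule(els, _zmat_to_cart(z))
    return perceive_bonds(mol)
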