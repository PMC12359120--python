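"""Torsion-scan ingestion and cosine-series amplitude refitting.

Given reference energies along a dihedral rotation, the amplitudes A_i
of the torsion terms V(phi) = sum_i A_i [1 + cos(p_i phi - phi0_i)]
registered on that bond are re-determined by linear least squares
against the residual E_ref(phi) - E_MM,rest(phi), where E_MM,rest is
the force-field energy with the fitted amplitudes zeroed. A free
additive constant absorbs the arbitrary zero of the reference data and
is discarded after the solve. Torsion terms on equivalent quadruples
sharing the same central bond are tied to one amplitude per (p, phi0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_core import Molecule, ParseError, read_xyz, set_dihedral_in_degrees
from .data import HARTREE_TO_KJMOL
from . import geometry as geom
from .mm_forcefield import DihedralTerm, FitReport, ForceField, evaluate

_UNIT_FACTORS = {
    "hartree": HARTREE_TO_KJMOL,
    "au": HARTREE_TO_KJMOL,
    "kj/mol": 1.0,
    "kjmol": 1.0,
    "kcal/mol": 4.184,
    "ev": 96.4853321233,
}


@dataclass
class DihedralScan:
    """Angles (deg), zero-shifted reference energies (kJ/mol) and optional geometries."""

    quad: tuple[int, int, int, int]
    angles: np.ndarray
    energies: np.ndarray
    geometries: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.quad = tuple(int(i) for i in self.quad)  # type: ignore[assignment]
        self.angles = np.asarray(self.angles, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if len(self.angles) != len(self.energies):
            raise ValueError("angle and energy counts differ")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("non-finite scan energies")
        self.energies = self.energies - self.energies.min()

    def __len__(self) -> int:
        return len(self.angles)


def read_scan_file(path) -> DihedralScan:
    """Read a multi-frame XYZ scan file.

    Each frame's comment line follows the dialect
    ``Scan <i>-<j>-<k>-<l> Dihedral <deg> Energy <value> [unit]``
    with 1-based atom labels and hartree as the default energy unit.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frames: list[Molecule] = []
    angles: list[float] = []
    energies: list[float] = []
    quad: tuple[int, int, int, int] | None = None
    frame_no = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        frame_no += 1
        try:
            n = int(lines[pos].strip())
        except ValueError:
            raise ParseError(f"frame {frame_no}: expected atom count, got '{lines[pos]}'")
        block = "\n".join(lines[pos : pos + n + 2])
        mol = read_xyz(block)
        tokens = lines[pos + 1].split()
        try:
            assert tokens[0].lower() == "scan"
            q = tuple(int(s) - 1 for s in tokens[1].replace("–", "-").split("-"))
            assert len(q) == 4
            assert tokens[2].lower() == "dihedral"
            ang = float(tokens[3])
            assert tokens[4].lower() == "energy"
            val = float(tokens[5])
            unit = tokens[6].lower() if len(tokens) > 6 else "hartree"
            factor = _UNIT_FACTORS[unit]
        except (AssertionError, IndexError, ValueError, KeyError):
            raise ParseError(
                f"frame {frame_no}: comment line '{lines[pos + 1]}' does not follow "
                "'Scan i-j-k-l Dihedral <deg> Energy <value> [unit]'"
            )
        if quad is None:
            quad = q  # type: ignore[assignment]
        elif q != quad:
            raise ParseError(f"frame {frame_no}: scan dihedral changed mid-file")
        if frames and mol.natoms != frames[0].natoms:
            raise ParseError(f"frame {frame_no}: atom count differs from frame 1")
        frames.append(mol)
        angles.append(ang)
        energies.append(val * factor)
        pos += n + 2
    if quad is None:
        raise ParseError("no frames found in scan file")
    return DihedralScan(
        quad, np.array(angles), np.array(energies), [m.coordinates for m in frames]
    )


def write_scan_file(path, scan: DihedralScan, mol: Molecule, unit: str = "kj/mol") -> None:
    """Write a scan in the dialect :func:`read_scan_file` reads."""
    factor = _UNIT_FACTORS[unit.lower()]
    label = "-".join(str(i + 1) for i in scan.quad)
    with open(path, "w") as fh:
        for ang, e, x in zip(scan.angles, scan.energies, scan.geometries or []):
            fh.write(f"{mol.natoms}\n")
            fh.write(f"Scan {label} Dihedral {ang:.4f} Energy {e / factor:.10f} {unit}\n")
            for el, (xx, yy, zz) in zip(mol.elements, x):
                fh.write(f"{el:<3s} {xx:16.8f} {yy:16.8f} {zz:16.8f}\n")


def scan_geometries(mol: Molecule, scan: DihedralScan) -> list[np.ndarray]:
    """Scan geometries: stored frames if present, else rigid rotation of ``mol``."""
    if scan.geometries is not None:
        return scan.geometries
    out = []
    work = mol.copy()
    for ang in scan.angles:
        set_dihedral_in_degrees(work, scan.quad, float(ang))
        out.append(work.coordinates.copy())
    return out


def mm_scan(mol: Molecule, ff: ForceField, scan: DihedralScan) -> np.ndarray:
    """Relative MM energies along the scan, zero-shifted, same ordering as angles."""
    work = mol.copy()
    energies = []
    for x in scan_geometries(mol, scan):
        work.coordinates = x.copy()
        energies.append(evaluate(work, ff)[0]["total"])
    e = np.array(energies)
    return e - e.min()


def _tied_groups(ff: ForceField, quad) -> list[list[DihedralTerm]]:
    """Terms to fit: all terms whose quad shares the central bond, grouped by (p, phi0)."""
    j, k = quad[1], quad[2]
    bond = frozenset((j, k))
    groups: dict[tuple[int, float], list[DihedralTerm]] = {}
    for t in ff.dihedral_terms:
        if frozenset((t.quad[1], t.quad[2])) == bond:
            groups.setdefault((t.p, round(t.phi0, 10)), []).append(t)
    return list(groups.values())


def _select_extrema(angles: np.ndarray, energies: np.ndarray) -> np.ndarray:
    """Indices of interior extrema by sign change of periodic finite differences.

    A full 360 deg scan is treated periodically; otherwise the endpoints
    are never selected.
    """
    order = np.argsort(angles)
    a = angles[order]
    e = energies[order]
    n = len(a)
    span = a[-1] - a[0]
    periodic = span >= 360.0 - 2.0 * (360.0 / max(n, 1))
    picked = []
    for idx in range(n):
        if not periodic and (idx == 0 or idx == n - 1):
            continue
        prev, nxt = (idx - 1) % n, (idx + 1) % n
        d1 = e[idx] - e[prev]
        d2 = e[nxt] - e[idx]
        if d1 * d2 <= 0 and not (d1 == 0 and d2 == 0):
            picked.append(order[idx])
    return np.array(sorted(picked), dtype=int)


def fit_dihedral(
    mol: Molecule,
    ff: ForceField,
    quad,
    scan: DihedralScan,
    fit_extrema: bool = False,
) -> ForceField:
    """Least-squares refit of the torsion amplitudes on ``quad``'s central bond.

    The force field is updated in place and returned; a
    :class:`~ffcraft.mm_forcefield.FitReport` with the RMSE and maximum
    deviation over the selected points is attached as
    ``ff.last_fit_report``.
    """
    quad = tuple(quad)
    groups = _tied_groups(ff, quad)
    if not groups:
        raise ValueError(f"no dihedral terms registered on the central bond of {quad}")
    geometries = scan_geometries(mol, scan)

    sel = np.arange(len(scan))
    if fit_extrema:
        sel = _select_extrema(scan.angles, scan.energies)
        if len(sel) == 0:
            raise ValueError("no interior extrema found in the scan")
    n_unknowns = len(groups) + 1  # + free constant
    if len(sel) < n_unknowns:
        raise ValueError(
            f"{len(sel)} fit points for {n_unknowns} unknowns (amplitudes + offset)"
        )

    # rest-of-force-field energies with fitted amplitudes zeroed
    saved = [(t, t.A) for g in groups for t in g]
    for t, _ in saved:
        t.A = 0.0
    work = mol.copy()
    rest = np.empty(len(scan))
    basis = np.empty((len(scan), len(groups)))
    for row, x in enumerate(geometries):
        work.coordinates = x.copy()
        rest[row] = evaluate(work, ff)[0]["total"]
        for col, g in enumerate(groups):
            basis[row, col] = sum(
                1.0 + np.cos(t.p * geom.dihedral_value(x, *t.quad) - t.phi0) for t in g
            )
    for t, a in saved:
        t.A = a

    design = np.hstack([basis[sel], np.ones((len(sel), 1))])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            "rank-deficient torsion basis: duplicate (p, phi0) terms or degenerate scan"
        )
    target = scan.energies[sel] - rest[sel]
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    amplitudes = coef[:-1]
    for amp, g in zip(amplitudes, groups):
        for t in g:
            t.A = float(amp)

    fitted = basis[sel] @ amplitudes + rest[sel] + coef[-1]
    resid = scan.energies[sel] - fitted
    ff.last_fit_report = FitReport(
        rmse=float(np.sqrt(np.mean(resid**2))),
        max_deviation=float(np.max(np.abs(resid))) if len(resid) else 0.0,
        n_points=len(sel),
        amplitudes={(g[0].p, g[0].phi0): float(a) for g, a in zip(groups, amplitudes)},
    )
    return ff


def add_fit_term(ff: ForceField, quad, periodicity: int, phase: float) -> ForceField:
    """Register a new torsion term with A = 0 (phase in degrees).

    The MM curve is unchanged until the next refit; duplicate (p, phi0)
    on the same quadruple is an error.
    """
    quad = tuple(quad)
    phi0 = float(np.radians(phase))
    for t in ff.terms_on_quad(quad):
        if t.p == periodicity and abs(geom.wrap_angle(t.phi0 - phi0)) < 1e-9:
            raise ValueError(
                f"term (p={periodicity}, phase={phase} deg) already present on {quad}"
            )
    ff.dihedral_terms.append(DihedralTerm(quad, 0.0, periodicity, phi0))
    return ff
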