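"""Interpolation-mechanics (IM) potential.

The potential energy surface is approximated as a distance-weighted sum
of second-order Taylor expansions stored at reference geometries:

    E(x) = sum_k w_k(x) [ E_k + g_k^T dq + 1/2 dq^T H_k dq ],

with dq the displacement in redundant internal coordinates (bond
lengths, valence angles, torsions; torsion components wrapped into
(-pi, pi]) and weights w_k built from the best-fit Cartesian RMSD
between the query and each reference structure. Two weighting modes are
supported: a one-part inverse-power form d^(-2p) and a modified
Shepard form [(d/r_k)^(2p) + (d/r_k)^(2q)]^(-1) with per-point
confidence radii r_k.

Derivatives at reference points are transformed from Cartesian to
internal coordinates through the Wilson B-matrix; the database is built
adaptively against a pluggable oracle (any callable x -> (E, gradient,
Hessian)) by seeding relaxed structures along a key torsion and
sampling restrained dynamics on the current IM surface, adding a point
whenever the IM error exceeds a threshold (default 8.4 kJ/mol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import h5py
import numpy as np

from .chem_core import (
    GeometryError,
    Molecule,
    angles_from_bonds,
    dihedrals_from_bonds,
    set_dihedral_in_degrees,
)
from .dynamics import langevin
from . import geometry as geom

DEFAULT_DB_NAME = "im_database.h5"
_FORMAT_VERSION = 1
_EXACT_HIT = 1e-10

Oracle = Callable[[np.ndarray], tuple[float, np.ndarray, np.ndarray]]


class IMDatabaseError(ValueError):
    """Malformed or foreign database container."""


# ---------------------------------------------------------------------------
# Internal coordinates


@dataclass(frozen=True)
class InternalCoordinateSet:
    bonds: tuple
    angles: tuple
    dihedrals: tuple

    @property
    def size(self) -> int:
        return len(self.bonds) + len(self.angles) + len(self.dihedrals)

    @property
    def periodic_mask(self) -> np.ndarray:
        m = np.zeros(self.size, dtype=bool)
        m[len(self.bonds) + len(self.angles) :] = True
        return m

    def values(self, x: np.ndarray) -> np.ndarray:
        q = np.empty(self.size)
        i = 0
        for a, b in self.bonds:
            q[i] = geom.bond_value(x, a, b)
            i += 1
        for a, b, c in self.angles:
            q[i] = geom.angle_value(x, a, b, c)
            i += 1
        for quad in self.dihedrals:
            q[i] = geom.dihedral_value(x, *quad)
            i += 1
        return q

    def b_matrix(self, x: np.ndarray) -> np.ndarray:
        """Wilson B-matrix dq/dx, shape (n_internal, 3N)."""
        n = len(x)
        B = np.zeros((self.size, 3 * n))
        row = 0
        for a, b in self.bonds:
            _, g = geom.bond_grad(x, a, b)
            for idx, v in g.items():
                B[row, 3 * idx : 3 * idx + 3] = v
            row += 1
        for a, b, c in self.angles:
            _, g = geom.angle_grad(x, a, b, c)
            for idx, v in g.items():
                B[row, 3 * idx : 3 * idx + 3] = v
            row += 1
        for quad in self.dihedrals:
            _, g = geom.dihedral_grad(x, *quad)
            for idx, v in g.items():
                B[row, 3 * idx : 3 * idx + 3] = v
            row += 1
        return B


def build_internal_coordinates(mol: Molecule) -> InternalCoordinateSet:
    """Redundant internal coordinates from the bond graph, deterministic order.

    Near-linear angles (> 175 deg) are kept but reported through the
    returned set's ``flagged_linear`` attribute is not maintained;
    callers relying on curvilinear behavior should inspect geometries.
    """
    if not mol.bonds:
        raise ValueError("bond graph empty: perceive bonds first")
    bonds = tuple(sorted(mol.bonds))
    angles = tuple(angles_from_bonds(mol))
    dihedrals = tuple(dihedrals_from_bonds(mol))
    return InternalCoordinateSet(bonds, angles, dihedrals)


def flag_linear_angles(mol: Molecule, ics: InternalCoordinateSet, limit_deg: float = 175.0):
    """Angle triples whose current value exceeds ``limit_deg`` (ill-conditioned rows)."""
    x = mol.coordinates
    return [
        trip
        for trip in ics.angles
        if math.degrees(geom.angle_value(x, *trip)) > limit_deg
    ]


def transform_derivatives(
    x: np.ndarray,
    g_cart: np.ndarray,
    h_cart: np.ndarray,
    ics: InternalCoordinateSet,
    fd_step: float = 1e-5,
    svd_cutoff: float = 1e-8,
):
    """Cartesian -> internal transformation of gradient and Hessian.

    g_int solves B^T g_int = g_cart in the least-squares sense via the
    generalized inverse of G = B B^T; the Hessian transformation removes
    the B-matrix curvature term sum_m (g_int)_m dB_m/dx, with dB/dx by
    central finite differences (step ``fd_step`` Å). Singular values
    below ``svd_cutoff`` relative to the largest are discarded.
    """
    n3 = 3 * len(x)
    g_flat = np.asarray(g_cart, dtype=float).reshape(n3)
    h_cart = np.asarray(h_cart, dtype=float).reshape(n3, n3)
    B = ics.b_matrix(x)
    sv = np.linalg.svd(B, compute_uv=False)
    n_independent = min(ics.size, n3 - 6)
    if np.sum(sv > svd_cutoff * sv[0]) < n_independent:
        raise GeometryError(
            "rank collapse in internal-coordinate set: "
            f"{np.sum(sv > svd_cutoff * sv[0])} independent rows, need {n_independent}"
        )
    b_plus = np.linalg.pinv(B, rcond=svd_cutoff)  # (3N, M)
    g_int = b_plus.T @ g_flat

    # curvature correction: sum_m g_int[m] * d B[m, :] / dx
    correction = np.zeros((n3, n3))
    flat = x.reshape(-1)
    for t in range(n3):
        xp = flat.copy()
        xm = flat.copy()
        xp[t] += fd_step
        xm[t] -= fd_step
        dB = (ics.b_matrix(xp.reshape(-1, 3)) - ics.b_matrix(xm.reshape(-1, 3))) / (
            2.0 * fd_step
        )
        correction[:, t] = g_int @ dB
    h_int = b_plus.T @ (h_cart - correction) @ b_plus
    h_int = 0.5 * (h_int + h_int.T)
    return ics.values(x), g_int, h_int


# ---------------------------------------------------------------------------
# Database


@dataclass
class IMDataPoint:
    q: np.ndarray
    energy: float
    gradient: np.ndarray  # internal
    hessian: np.ndarray  # internal, symmetric
    x_ref: np.ndarray  # (N, 3) Å
    radius: float  # confidence radius in the RMSD metric

    def __post_init__(self) -> None:
        self.hessian = np.asarray(self.hessian, dtype=float)
        if not np.allclose(self.hessian, self.hessian.T, atol=1e-8):
            raise ValueError("internal Hessian must be symmetric")


@dataclass
class IMDatabase:
    ics: InternalCoordinateSet
    points: list[IMDataPoint] = field(default_factory=list)
    weight_mode: str = "shepard"  # or "one-part"
    exponent_2p: int = 12
    exponent_2q: int = 2
    default_radius: float = 0.5  # Å, used until a point has a neighbor

    def __post_init__(self) -> None:
        if self.weight_mode not in ("shepard", "one-part"):
            raise ValueError(f"unknown weight mode '{self.weight_mode}'")
        self._stack = None

    def __len__(self) -> int:
        return len(self.points)

    def invalidate_cache(self) -> None:
        self._stack = None

    def _stacked(self):
        """Stacked point arrays (x_refs, q, E, g, H, r) for vectorized evaluation."""
        if self._stack is None or len(self._stack[2]) != len(self.points):
            self._stack = (
                np.stack([p.x_ref for p in self.points]),
                np.stack([p.q for p in self.points]),
                np.array([p.energy for p in self.points]),
                np.stack([p.gradient for p in self.points]),
                np.stack([p.hessian for p in self.points]),
                np.array([p.radius for p in self.points]),
            )
        return self._stack


def taylor_energy_gradient(q: np.ndarray, point: IMDataPoint, periodic_mask: np.ndarray):
    """Second-order Taylor value and internal gradient at internal coords q."""
    dq = np.asarray(q, dtype=float) - point.q
    dq[periodic_mask] = geom.wrap_angle(dq[periodic_mask])
    hdq = point.hessian @ dq
    e = point.energy + point.gradient @ dq + 0.5 * dq @ hdq
    return float(e), point.gradient + hdq


def _raw_weight_and_derivative(d: float, r: float, mode: str, p2: int, q2: int):
    """Unnormalized weight v(d) and dv/dd."""
    if mode == "one-part":
        v = d ** (-p2)
        dv = -p2 * d ** (-p2 - 1)
    else:
        t_p = (d / r) ** p2
        t_q = (d / r) ** q2
        v = 1.0 / (t_p + t_q)
        dv = -(v * v) * (p2 * t_p + q2 * t_q) / d
    return v, dv


def _raw_weights_vec(d: np.ndarray, r: np.ndarray, mode: str, p2: int, q2: int):
    """Vectorized unnormalized weights and derivatives over all points."""
    if mode == "one-part":
        v = d ** (-p2)
        dv = -p2 * d ** (-p2 - 1)
    else:
        t_p = (d / r) ** p2
        t_q = (d / r) ** q2
        v = 1.0 / (t_p + t_q)
        dv = -(v * v) * (p2 * t_p + q2 * t_q) / d
    return v, dv


def shepard_weights(x: np.ndarray, db: IMDatabase) -> np.ndarray:
    """Normalized interpolation weights of the stored points for geometry x."""
    if not db.points:
        raise ValueError("empty database")
    xs, _, _, _, _, radii = db._stacked()
    d, _ = geom.kabsch_rmsd_gradient_many(np.asarray(x, dtype=float), xs)
    w = np.zeros(len(d))
    hit = np.argmin(d)
    if d[hit] < _EXACT_HIT:
        w[hit] = 1.0
        return w
    v, _ = _raw_weights_vec(d, radii, db.weight_mode, db.exponent_2p, db.exponent_2q)
    return v / v.sum()


def im_energy_gradient(x: np.ndarray, db: IMDatabase):
    """IM energy (kJ/mol) and Cartesian gradient (kJ/mol/Å) at geometry x."""
    if not db.points:
        raise ValueError("empty database")
    ics = db.ics
    q = ics.values(x)
    B = ics.b_matrix(x)
    mask = ics.periodic_mask
    xs, qs, es, gs, hs, radii = db._stacked()

    dists, dgrads = geom.kabsch_rmsd_gradient_many(x, xs)
    hit = int(np.argmin(dists))

    # stacked Taylor expansions: dq wraps torsion components
    dq = q[None, :] - qs
    dq[:, mask] = geom.wrap_angle(dq[:, mask])
    hdq = np.einsum("pmn,pn->pm", hs, dq)
    energies = es + np.einsum("pm,pm->p", gs, dq) + 0.5 * np.einsum("pm,pm->p", dq, hdq)
    gq = gs + hdq  # (P, M) internal gradients

    if dists[hit] < _EXACT_HIT:
        return float(energies[hit]), (B.T @ gq[hit]).reshape(-1, 3)

    v, dv = _raw_weights_vec(dists, radii, db.weight_mode, db.exponent_2p, db.exponent_2q)
    s = v.sum()
    w = v / s
    sum_dv_grad = np.einsum("p,pnc->nc", dv, dgrads)
    dw = (dv[:, None, None] * dgrads - w[:, None, None] * sum_dv_grad[None]) / s
    grad = np.einsum("p,pnc->nc", energies, dw) + (B.T @ (w @ gq)).reshape(-1, 3)
    return float(w @ energies), grad


def im_energy(x: np.ndarray, db: IMDatabase) -> float:
    return im_energy_gradient(x, db)[0]


def _recompute_radii(db: IMDatabase) -> None:
    """Confidence radius of each point = distance to its nearest neighbor."""
    db.invalidate_cache()
    pts = db.points
    if len(pts) < 2:
        for p in pts:
            p.radius = db.default_radius
        return
    for i, p in enumerate(pts):
        p.radius = min(
            geom.kabsch_rmsd(p.x_ref, o.x_ref) for j, o in enumerate(pts) if j != i
        )


def add_point(x: np.ndarray, oracle: Oracle, db: IMDatabase) -> IMDatabase:
    """Evaluate the oracle at x, transform derivatives, and append a data point.

    Geometries within 1e-6 RMSD of a stored point are rejected with a
    warning (the database is returned unchanged).
    """
    import warnings

    x = np.asarray(x, dtype=float)
    for p in db.points:
        if geom.kabsch_rmsd(x, p.x_ref) < 1e-6:
            warnings.warn("geometry already in database; point rejected")
            return db
    e, g, h = oracle(x)
    q, g_int, h_int = transform_derivatives(x, g, h, db.ics)
    db.points.append(IMDataPoint(q, float(e), g_int, h_int, x.copy(), db.default_radius))
    _recompute_radii(db)
    return db


# ---------------------------------------------------------------------------
# Persistence


def save_database(db: IMDatabase, path: str = DEFAULT_DB_NAME) -> str:
    with h5py.File(path, "w") as fh:
        meta = fh.create_group("meta")
        meta.attrs["mode"] = db.weight_mode
        meta.attrs["exponents"] = (db.exponent_2p, db.exponent_2q)
        meta.attrs["version"] = _FORMAT_VERSION
        meta.attrs["default_radius"] = db.default_radius
        coords = fh.create_group("coords")
        coords.create_dataset("bonds", data=np.array(db.ics.bonds, dtype=int).reshape(-1, 2))
        coords.create_dataset("angles", data=np.array(db.ics.angles, dtype=int).reshape(-1, 3))
        coords.create_dataset(
            "dihedrals", data=np.array(db.ics.dihedrals, dtype=int).reshape(-1, 4)
        )
        pts = fh.create_group("points")
        for k, p in enumerate(db.points):
            g = pts.create_group(str(k))
            g.create_dataset("q", data=p.q)
            g.create_dataset("E", data=p.energy)
            g.create_dataset("g", data=p.gradient)
            g.create_dataset("H", data=p.hessian)
            g.create_dataset("x", data=p.x_ref)
            g.create_dataset("r", data=p.radius)
    return path


def load_database(path: str = DEFAULT_DB_NAME) -> IMDatabase:
    try:
        with h5py.File(path, "r") as fh:
            if "meta" not in fh or "coords" not in fh or "points" not in fh:
                raise IMDatabaseError(
                    f"'{path}' is not an IM database (format version {_FORMAT_VERSION})"
                )
            meta = fh["meta"].attrs
            ics = InternalCoordinateSet(
                tuple(map(tuple, fh["coords/bonds"][()].tolist())),
                tuple(map(tuple, fh["coords/angles"][()].tolist())),
                tuple(map(tuple, fh["coords/dihedrals"][()].tolist())),
            )
            p2, q2 = (int(v) for v in meta["exponents"])
            db = IMDatabase(
                ics,
                weight_mode=str(meta["mode"]),
                exponent_2p=p2,
                exponent_2q=q2,
                default_radius=float(meta.get("default_radius", 0.5)),
            )
            for k in sorted(fh["points"], key=int):
                g = fh["points"][k]
                db.points.append(
                    IMDataPoint(
                        g["q"][()],
                        float(g["E"][()]),
                        g["g"][()],
                        g["H"][()],
                        g["x"][()],
                        float(g["r"][()]),
                    )
                )
            return db
    except OSError as exc:
        raise IMDatabaseError(
            f"cannot read '{path}' as an IM database (format version {_FORMAT_VERSION}): {exc}"
        ) from None


# ---------------------------------------------------------------------------
# Adaptive construction


@dataclass
class IMBuildSettings:
    """Protocol constants for adaptive database construction.

    Defaults follow the torsion-scan protocol: ten oracle-relaxed seed
    structures equidistant over the full rotation, sampling dynamics
    restrained to ±18 deg around each seed, an 8.4 kJ/mol IM-vs-oracle
    energy threshold for adding points, and termination of a sampling
    run after 7.5 ps without additions.
    """

    energy_threshold: float = 8.4  # kJ/mol
    max_points: int = 60
    no_add_window_ps: float = 7.5
    n_seed_structures: int = 10
    displacement_restraint_deg: float = 18.0
    timestep_fs: float = 0.5
    temperature: float = 300.0
    friction_per_ps: float = 5.0
    restraint_k: float = 500.0  # kJ/mol/rad^2, flat-bottom wall
    seed: int = 0
    check_interval: int = 1  # steps between IM-vs-oracle checks
    max_quality_iterations: int = 10
    quality_sim_ps: float = 2.0

    def __post_init__(self) -> None:
        if self.energy_threshold <= 0:
            raise ValueError("energy threshold must be positive")
        if self.no_add_window_ps <= 0:
            raise ValueError("no-add window must be positive")


class ConvergenceError(RuntimeError):
    """Carries the partially built database when iteration caps are hit."""

    def __init__(self, message: str, database: IMDatabase | None = None):
        super().__init__(message)
        self.database = database


def _oracle_energy_gradient(oracle: Oracle, x: np.ndarray):
    """Energy and gradient only; skips the Hessian when the oracle allows it."""
    fast = getattr(oracle, "energy_gradient", None)
    if fast is not None:
        return fast(x)
    e, g, _ = oracle(x)
    return e, g


def relax_with_frozen_dihedral(
    mol: Molecule,
    oracle: Oracle,
    quad: Sequence[int],
    target_deg: float,
    gtol: float = 0.1,
    max_iter: int = 5000,
) -> Molecule:
    """Oracle gradient descent with the scanned dihedral frozen at ``target_deg``.

    Backtracking line search on the oracle energy; the torsion component
    of the gradient is projected out and the dihedral re-imposed after
    every step. Converges at max |g_perp| < ``gtol`` kJ/mol/Å.
    """
    work = mol.copy()
    set_dihedral_in_degrees(work, quad, target_deg)
    step = 1e-3
    e, g = _oracle_energy_gradient(oracle, work.coordinates)
    for it in range(max_iter):
        b = np.zeros(3 * work.natoms)
        _, dg = geom.dihedral_grad(work.coordinates, *quad)
        for idx, v in dg.items():
            b[3 * idx : 3 * idx + 3] = v
        gf = g.reshape(-1)
        g_perp = (gf - (gf @ b) / (b @ b) * b).reshape(-1, 3)
        if np.abs(g_perp).max() < gtol:
            return work
        while step > 1e-12:
            trial = work.copy()
            trial.coordinates = work.coordinates - step * g_perp
            set_dihedral_in_degrees(trial, quad, target_deg)
            e_t, g_t = _oracle_energy_gradient(oracle, trial.coordinates)
            if e_t < e:
                work, e, g = trial, e_t, g_t
                step *= 1.5
                break
            step *= 0.5
        else:
            raise ConvergenceError(
                f"line search stalled at iteration {it}, max|g_perp|="
                f"{np.abs(g_perp).max():.3g} kJ/mol/Å"
            )
    raise ConvergenceError(
        f"frozen-dihedral relaxation did not converge in {max_iter} iterations"
    )


def _restraint_force(x: np.ndarray, quad, center_deg: float, half_width_deg: float, k: float):
    """Flat-bottom harmonic wall on the torsion outside ±half_width around center."""
    phi, dg = geom.dihedral_grad(x, *quad)
    delta = geom.wrap_angle(phi - math.radians(center_deg))
    wall = math.radians(half_width_deg)
    excess = abs(delta) - wall
    f = np.zeros_like(x)
    if excess > 0:
        dEdphi = k * excess * math.copysign(1.0, delta)
        for idx, v in dg.items():
            f[idx] -= dEdphi * v
    return f


def build_database(
    mol: Molecule,
    oracle: Oracle,
    key_dihedral: Sequence[int],
    settings: IMBuildSettings | None = None,
    db: IMDatabase | None = None,
) -> tuple[IMDatabase, list[dict]]:
    """Adaptive IM database construction along a key torsion.

    Seeds ``n_seed_structures`` oracle-relaxed geometries equidistant
    over the full 360 deg rotation. After adding each seed, samples
    restrained Langevin dynamics on the current IM surface and adds any
    structure whose IM-vs-oracle energy error exceeds the threshold; a
    sampling run ends once no point has been added for
    ``no_add_window_ps``. Returns the database and a per-seed build log.
    """
    settings = settings or IMBuildSettings()
    quad = tuple(key_dihedral)
    if db is None:
        db = IMDatabase(build_internal_coordinates(mol))
    log: list[dict] = []
    if len(db) >= settings.max_points:
        return db, log
    masses = mol.masses
    rng = np.random.default_rng(settings.seed)
    window_steps = int(round(settings.no_add_window_ps * 1000.0 / settings.timestep_fs))
    check = max(settings.check_interval, 1)

    start_angle = geom.dihedral_value(mol.coordinates, *quad)
    seed_angles = math.degrees(start_angle) + np.arange(settings.n_seed_structures) * (
        360.0 / settings.n_seed_structures
    )

    for seed_no, ang in enumerate(seed_angles):
        relaxed = relax_with_frozen_dihedral(mol, oracle, quad, float(ang))
        before = len(db)
        add_point(relaxed.coordinates, oracle, db)
        entry = {
            "seed_angle": float(ang),
            "seed_added": len(db) > before,
            "points_added": 0,
            "steps": 0,
        }
        state = {"since_add": 0, "e_im": 0.0}

        def force(x):
            e, g = im_energy_gradient(x, db)
            state["e_im"] = e  # reused by the monitor to avoid re-evaluation
            return -g + _restraint_force(
                x, quad, ang, settings.displacement_restraint_deg, settings.restraint_k
            )

        def monitor(step, x):
            state["since_add"] += 1
            entry["steps"] = step + 1
            if step % check == 0 and len(db) < settings.max_points:
                e_im = state["e_im"]
                e_ref = _oracle_energy_gradient(oracle, x)[0]
                if abs(e_im - e_ref) > settings.energy_threshold:
                    n0 = len(db)
                    add_point(x, oracle, db)
                    if len(db) > n0:
                        entry["points_added"] += 1
                        state["since_add"] = 0
            if state["since_add"] >= window_steps:
                return True
            if len(db) >= settings.max_points:
                return True
            return None

        max_steps = 50 * window_steps  # hard cap against pathological oracles
        langevin(
            relaxed.coordinates,
            masses,
            force,
            n_steps=max_steps,
            timestep_fs=settings.timestep_fs,
            temperature=settings.temperature,
            friction_per_ps=settings.friction_per_ps,
            rng=np.random.default_rng(settings.seed * 100003 + seed_no),
            callback=monitor,
        )
        log.append(entry)
        if len(db) >= settings.max_points:
            break
    return db, log


def confirm_database_quality(
    mol: Molecule,
    db: IMDatabase,
    oracle: Oracle,
    settings: IMBuildSettings | None = None,
) -> tuple[list[dict], IMDatabase]:
    """Validate the IM surface with test dynamics; expand until convergent.

    Each iteration runs an unrestrained Langevin test simulation on the
    IM surface, recording the maximum |E_IM - E_oracle| and adding every
    structure above the threshold. Convergence is a full pass with zero
    additions; exceeding ``max_quality_iterations`` raises
    :class:`ConvergenceError` carrying the partial database.
    """
    settings = settings or IMBuildSettings()
    if not db.points:
        raise ValueError("cannot validate an empty database")
    masses = mol.masses
    n_steps = int(round(settings.quality_sim_ps * 1000.0 / settings.timestep_fs))
    check = max(settings.check_interval, 1)
    report: list[dict] = []
    for it in range(settings.max_quality_iterations):
        added = 0
        max_err = 0.0
        state = {"e_im": 0.0}

        def force(x):
            e, g = im_energy_gradient(x, db)
            state["e_im"] = e
            return -g

        def monitor(step, x):
            nonlocal added, max_err
            if step % check:
                return None
            err = abs(state["e_im"] - _oracle_energy_gradient(oracle, x)[0])
            max_err = max(max_err, err)
            if err > settings.energy_threshold and len(db) < settings.max_points:
                n0 = len(db)
                add_point(x, oracle, db)
                if len(db) > n0:
                    added += 1
            return None

        langevin(
            db.points[0].x_ref,
            masses,
            force,
            n_steps=n_steps,
            timestep_fs=settings.timestep_fs,
            temperature=settings.temperature,
            friction_per_ps=settings.friction_per_ps,
            rng=np.random.default_rng(settings.seed * 7919 + it),
            callback=monitor,
        )
        report.append({"iteration": it, "max_error": max_err, "additions": added})
        if added == 0:
            return report, db
    raise ConvergenceError(
        f"quality loop did not converge in {settings.max_quality_iterations} iterations",
        database=db,
    )
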