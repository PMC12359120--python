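"""Internal-coordinate values, their Cartesian first derivatives, and
best-fit superposition (Kabsch) utilities.

These primitives back the force-field energy/gradient evaluation, the
Wilson B-matrix of the interpolation potential, and RMSD-based structure
comparison. All angles are in radians here; degrees appear only at user
surfaces.
"""

from __future__ import annotations

import numpy as np


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # np.cross has high call overhead for single 3-vectors
    return np.array(
        [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
    )


def bond_value(x: np.ndarray, a: int, b: int) -> float:
    return float(np.linalg.norm(x[a] - x[b]))


def bond_grad(x: np.ndarray, a: int, b: int):
    """Bond length and its gradient with respect to atoms a and b."""
    r = x[a] - x[b]
    d = np.linalg.norm(r)
    u = r / d
    return float(d), {a: u, b: -u}


def angle_value(x: np.ndarray, a: int, b: int, c: int) -> float:
    u = x[a] - x[b]
    v = x[c] - x[b]
    cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cos, -1.0, 1.0)))


def angle_grad(x: np.ndarray, a: int, b: int, c: int):
    """Valence angle a-b-c (rad) and its Cartesian gradient."""
    u = x[a] - x[b]
    v = x[c] - x[b]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    uh, vh = u / nu, v / nv
    cos = np.clip(np.dot(uh, vh), -1.0, 1.0)
    sin = np.sqrt(max(1.0 - cos * cos, 1e-16))
    theta = float(np.arccos(cos))
    ga = (cos * uh - vh) / (nu * sin)
    gc = (cos * vh - uh) / (nv * sin)
    return theta, {a: ga, b: -(ga + gc), c: gc}


def dihedral_value(x: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Torsion angle in radians, IUPAC sign, range (-pi, pi]."""
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    m = _cross(n1, b2 / np.linalg.norm(b2))
    phi = float(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))
    if phi <= -np.pi:
        phi += 2 * np.pi
    return phi


def dihedral_grad(x: np.ndarray, i: int, j: int, k: int, l: int):
    """Torsion angle (rad) and its Cartesian gradient (standard cross-product form)."""
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    gi = nb2 / np.dot(n1, n1) * n1
    gl = -nb2 / np.dot(n2, n2) * n2
    s12 = np.dot(b1, b2) / np.dot(b2, b2)
    s32 = np.dot(b3, b2) / np.dot(b2, b2)
    gj = -(1.0 + s12) * gi + s32 * gl
    gk = s12 * gi - (1.0 + s32) * gl
    phi = dihedral_value(x, i, j, k, l)
    return phi, {i: gi, j: gj, k: gk, l: gl}


def wrap_angle(dphi: np.ndarray | float):
    """Wrap angle difference(s) into (-pi, pi]."""
    out = np.mod(np.asarray(dphi, dtype=float) + np.pi, 2 * np.pi) - np.pi
    out = np.where(out == -np.pi, np.pi, out)
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# Superposition


def kabsch_rotation(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||p - q R^T|| for centered point sets."""
    h = q.T @ p
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.diag([1.0, 1.0, d])
    return (u @ s @ vt).T


def kabsch_rmsd(x: np.ndarray, y: np.ndarray, return_aligned: bool = False):
    """Best-fit RMSD between conformations x and y (same atom ordering).

    Optionally also returns y rotated/translated onto x and the centered
    copy of x, which the analytic RMSD gradient needs.
    """
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    r = kabsch_rotation(xc, yc)
    y_fit = yc @ r.T
    diff = xc - y_fit
    rmsd = float(np.sqrt((diff**2).sum() / len(x)))
    if return_aligned:
        return rmsd, xc, y_fit
    return rmsd


def kabsch_rmsd_gradient(x: np.ndarray, y: np.ndarray):
    """RMSD(x, y) and its gradient with respect to x.

    At the optimal superposition the rotation is stationary, so the
    envelope theorem gives d(rmsd)/dx = (x_c - y_fit) / (N * rmsd); the
    residual sums to zero so the centering projection is a no-op.
    """
    rmsd, xc, y_fit = kabsch_rmsd(x, y, return_aligned=True)
    n = len(x)
    if rmsd < 1e-12:
        return rmsd, np.zeros_like(x)
    return rmsd, (xc - y_fit) / (n * rmsd)


def kabsch_rmsd_gradient_many(x: np.ndarray, ys: np.ndarray):
    """Batched best-fit RMSDs and their gradients with respect to x.

    ``ys`` has shape (P, N, 3); returns (rmsds (P,), grads (P, N, 3)).
    Uses batched SVD; exact hits get a zero gradient.
    """
    n = len(x)
    xc = x - x.mean(axis=0)
    ycs = ys - ys.mean(axis=1, keepdims=True)
    h = np.einsum("pni,nj->pij", ycs, xc)
    u, _, vt = np.linalg.svd(h)
    det = np.sign(np.linalg.det(np.einsum("pij,pjk->pik", u, vt)))
    u[:, :, 2] *= det[:, None]
    m = np.einsum("pij,pjk->pik", u, vt)  # stacked u S vt = R^T
    y_fit = np.einsum("pni,pij->pnj", ycs, m)
    diff = xc[None, :, :] - y_fit
    rmsds = np.sqrt((diff**2).sum(axis=(1, 2)) / n)
    grads = np.zeros_like(diff)
    nz = rmsds > 1e-12
    grads[nz] = diff[nz] / (n * rmsds[nz, None, None])
    return rmsds, grads
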