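import math

import numpy as np
import pytest

from ffcraft.chem_core import set_dihedral_in_degrees
from ffcraft import geometry as geom
from ffcraft.interpolation_ff import (
    IMBuildSettings,
    IMDatabase,
    IMDatabaseError,
    add_point,
    build_database,
    build_internal_coordinates,
    confirm_database_quality,
    im_energy,
    im_energy_gradient,
    load_database,
    relax_with_frozen_dihedral,
    save_database,
    shepard_weights,
    taylor_energy_gradient,
    transform_derivatives,
)
from ffcraft.toy_oracles import harmonic_oracle, torsion_oracle
from tests.conftest import PEROXIDE_QUAD, PEROXIDE_TERMS, finite_difference_gradient

# reduced protocol for unit tests; the full default protocol runs in the
# acceptance suite
FAST = IMBuildSettings(
    n_seed_structures=4, no_add_window_ps=0.25, quality_sim_ps=0.4, seed=3
)


class QuadraticInternalOracle:
    """E = 1/2 sum_m k_m wrap(q_m - q0_m)^2 — exactly quadratic in internals.

    ``k`` may be a scalar or a per-coordinate vector. Note that a stiff
    torsion spring combined with reference points near the +-180 deg branch
    cut breaks multi-point Taylor composition (the wrap is not additive), so
    exactness tests spanning the full rotation zero the torsion stiffness.
    """

    def __init__(self, ics, x0, k=400.0):
        self.ics = ics
        self.q0 = ics.values(np.asarray(x0, dtype=float))
        self.k = np.broadcast_to(np.asarray(k, dtype=float), (ics.size,)).copy()
        self.mask = ics.periodic_mask

    def _dq(self, x):
        dq = self.ics.values(x) - self.q0
        dq[self.mask] = geom.wrap_angle(dq[self.mask])
        return dq

    def energy_gradient(self, x):
        dq = self._dq(x)
        B = self.ics.b_matrix(x)
        return float(0.5 * dq @ (self.k * dq)), (B.T @ (self.k * dq)).reshape(-1, 3)

    def __call__(self, x, h=1e-6):
        e, g = self.energy_gradient(x)
        n3 = x.size
        hess = np.zeros((n3, n3))
        flat = np.asarray(x, dtype=float).reshape(-1)
        for t in range(n3):
            xp, xm = flat.copy(), flat.copy()
            xp[t] += h
            xm[t] -= h
            hess[:, t] = (
                self.energy_gradient(xp.reshape(-1, 3))[1]
                - self.energy_gradient(xm.reshape(-1, 3))[1]
            ).reshape(-1) / (2 * h)
        return e, g, 0.5 * (hess + hess.T)


class TestInternalCoordinates:
    def test_water_counts(self, water):
        ics = build_internal_coordinates(water)
        assert (len(ics.bonds), len(ics.angles), len(ics.dihedrals)) == (2, 1, 0)

    def test_butane_counts_match_graph_walk(self, butane):
        ics = build_internal_coordinates(butane)
        n_angles = 0
        n_dihedrals = 0
        for b in range(butane.natoms):
            nb = len(butane.neighbors(b))
            n_angles += nb * (nb - 1) // 2
        for j, k in butane.bonds:
            n_dihedrals += (len(butane.neighbors(j)) - 1) * (len(butane.neighbors(k)) - 1)
        assert len(ics.bonds) == 13
        assert len(ics.angles) == n_angles
        assert len(ics.dihedrals) == n_dihedrals

    def test_deterministic_ordering(self, butane):
        a = build_internal_coordinates(butane)
        b = build_internal_coordinates(butane)
        assert a == b
        assert hash(a) == hash(b)

    def test_b_matrix_matches_finite_differences(self, peroxide):
        ics = build_internal_coordinates(peroxide)
        x = peroxide.coordinates + np.random.default_rng(0).normal(0, 0.02, (4, 3))
        B = ics.b_matrix(x)
        h = 1e-6
        for row in range(ics.size):
            for t in range(12):
                xp, xm = x.reshape(-1).copy(), x.reshape(-1).copy()
                xp[t] += h
                xm[t] -= h
                d = (
                    ics.values(xp.reshape(-1, 3))[row]
                    - ics.values(xm.reshape(-1, 3))[row]
                )
                if abs(d) > math.pi:
                    d -= math.copysign(2 * math.pi, d)
                assert abs(d / (2 * h) - B[row, t]) < 1e-7


class TestTransformDerivatives:
    def test_back_projection_identity(self, peroxide, peroxide_oracle):
        m = peroxide.copy()
        set_dihedral_in_degrees(m, PEROXIDE_QUAD, 77.0)
        x = m.coordinates + 0.01 * np.random.default_rng(1).normal(0, 1, (4, 3))
        ics = build_internal_coordinates(peroxide)
        e, g, h = peroxide_oracle(x)
        _, g_int, _ = transform_derivatives(x, g, h, ics)
        assert np.abs(ics.b_matrix(x).T @ g_int - g.reshape(-1)).max() < 1e-8

    def test_zero_input_zero_output(self, peroxide):
        ics = build_internal_coordinates(peroxide)
        q, g_int, h_int = transform_derivatives(
            peroxide.coordinates, np.zeros((4, 3)), np.zeros((12, 12)), ics
        )
        assert np.abs(g_int).max() == 0.0
        assert np.abs(h_int).max() < 1e-10

    def test_internal_hessian_reproduces_directional_curvature(
        self, peroxide, peroxide_oracle
    ):
        # chain-rule audit at a stationary geometry (zero gradient, so the
        # B-matrix curvature term vanishes): transformed derivatives rebuilt
        # into Cartesians must reproduce the oracle Hessian on the internal
        # subspace
        m = peroxide.copy()
        set_dihedral_in_degrees(m, PEROXIDE_QUAD, 180.0)  # torsion minimum
        x = m.coordinates
        ics = build_internal_coordinates(peroxide)
        e, g, h = peroxide_oracle(x)
        q, g_int, h_int = transform_derivatives(x, g, h, ics)
        B = ics.b_matrix(x)
        h_back = B.T @ h_int @ B  # g_int ~ 0 at the reference geometry
        # compare along internal-space directions only
        proj = B.T @ np.linalg.pinv(B).T
        diff = proj @ (h - h_back) @ proj.T
        assert np.abs(diff).max() < 1e-4


class TestTaylorAndWeights:
    def test_expansion_center_exact(self, peroxide_db):
        p = peroxide_db.points[0]
        mask = peroxide_db.ics.periodic_mask
        e, g = taylor_energy_gradient(p.q, p, mask)
        assert e == p.energy
        assert np.array_equal(g, p.gradient)

    def test_dihedral_wrapping(self, peroxide_db):
        p = peroxide_db.points[0]
        mask = peroxide_db.ics.periodic_mask
        q = p.q.copy()
        didx = np.flatnonzero(mask)[0]
        q[didx] = p.q[didx] + 2 * math.pi - math.radians(2.0)  # -2 deg after wrap
        e_wrap, _ = taylor_energy_gradient(q, p, mask)
        q[didx] = p.q[didx] - math.radians(2.0)
        e_direct, _ = taylor_energy_gradient(q, p, mask)
        assert e_wrap == pytest.approx(e_direct, abs=1e-12)

    def test_stored_geometry_gets_unit_weight(self, peroxide, peroxide_db):
        w = shepard_weights(peroxide_db.points[2].x_ref, peroxide_db)
        assert w[2] == 1.0
        assert w.sum() == 1.0
        assert np.count_nonzero(w) == 1

    def test_weights_normalized_and_nonnegative(self, peroxide, peroxide_db):
        rng = np.random.default_rng(4)
        for _ in range(100):
            x = peroxide.coordinates + rng.normal(0, 0.1, (4, 3))
            w = shepard_weights(x, peroxide_db)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(w >= 0)

    def test_equidistant_points_share_weight(self, peroxide, peroxide_oracle):
        db = IMDatabase(build_internal_coordinates(peroxide))
        for ang in (40.0, -40.0):  # mirror images: equidistant from 0
            m = peroxide.copy()
            set_dihedral_in_degrees(m, PEROXIDE_QUAD, ang)
            add_point(m.coordinates, peroxide_oracle, db)
        m0 = peroxide.copy()
        set_dihedral_in_degrees(m0, PEROXIDE_QUAD, 0.0)
        w = shepard_weights(m0.coordinates, db)
        assert w[0] == pytest.approx(w[1], rel=1e-6)

    def test_weights_match_direct_formula(self, peroxide, peroxide_db):
        x = peroxide.coordinates + np.random.default_rng(8).normal(0, 0.05, (4, 3))
        w = shepard_weights(x, peroxide_db)
        d = np.array([geom.kabsch_rmsd(x, p.x_ref) for p in peroxide_db.points])
        r = np.array([p.radius for p in peroxide_db.points])
        v = 1.0 / ((d / r) ** 12 + (d / r) ** 2)
        assert np.abs(w - v / v.sum()).max() < 1e-12


class TestIMEnergyGradient:
    def test_single_point_database_is_taylor(self, peroxide, peroxide_oracle):
        db = IMDatabase(build_internal_coordinates(peroxide))
        add_point(peroxide.coordinates, peroxide_oracle, db)
        x = peroxide.coordinates + 0.02
        mask = db.ics.periodic_mask
        e_t, _ = taylor_energy_gradient(db.ics.values(x), db.points[0], mask)
        assert im_energy(x, db) == pytest.approx(e_t, abs=1e-12)

    def test_interpolation_through_data(self, peroxide_db, peroxide_oracle):
        for p in peroxide_db.points:
            e_im, g_im = im_energy_gradient(p.x_ref, peroxide_db)
            e_o, g_o, _ = peroxide_oracle(p.x_ref)
            assert abs(e_im - e_o) < 1e-9
            assert np.abs(g_im - g_o).max() < 1e-6

    def test_gradient_matches_finite_differences(self, peroxide, peroxide_db):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = peroxide.copy()
            set_dihedral_in_degrees(m, PEROXIDE_QUAD, rng.uniform(-180, 180))
            x = m.coordinates + rng.normal(0, 0.02, (4, 3))
            _, g = im_energy_gradient(x, peroxide_db)
            fd = finite_difference_gradient(lambda y: im_energy(y, peroxide_db), x)
            assert np.abs(fd - g).max() < 1e-5

    def test_rigid_motion_invariance(self, peroxide, peroxide_db):
        from scipy.spatial.transform import Rotation

        x = peroxide.coordinates + np.random.default_rng(2).normal(0, 0.03, (4, 3))
        e1 = im_energy(x, peroxide_db)
        rot = Rotation.from_euler("xyz", [0.7, -1.1, 0.3]).as_matrix()
        e2 = im_energy(x @ rot.T + np.array([4.0, 5.0, -6.0]), peroxide_db)
        assert e2 == pytest.approx(e1, abs=1e-9)

    def test_quadratic_internal_oracle_single_point_exact(self, peroxide):
        # potential exactly quadratic in the internal coordinates: a single
        # Taylor expansion reproduces it at any displacement
        ics = build_internal_coordinates(peroxide)
        oracle = QuadraticInternalOracle(ics, peroxide.coordinates)
        db = IMDatabase(build_internal_coordinates(peroxide))
        add_point(peroxide.coordinates, oracle, db)
        rng = np.random.default_rng(6)
        for _ in range(5):
            m = peroxide.copy()
            set_dihedral_in_degrees(m, PEROXIDE_QUAD, rng.uniform(-180, 180))
            x = m.coordinates + rng.normal(0, 0.03, (4, 3))
            assert im_energy(x, db) == pytest.approx(oracle(x)[0], abs=1e-4)


class TestAddPointAndPersistence:
    def test_add_point_increments_and_reproduces(self, peroxide, peroxide_oracle):
        db = IMDatabase(build_internal_coordinates(peroxide))
        add_point(peroxide.coordinates, peroxide_oracle, db)
        assert len(db) == 1
        assert im_energy(peroxide.coordinates, db) == pytest.approx(
            peroxide_oracle(peroxide.coordinates)[0], abs=1e-12
        )

    def test_duplicate_rejected_with_warning(self, peroxide, peroxide_oracle):
        db = IMDatabase(build_internal_coordinates(peroxide))
        add_point(peroxide.coordinates, peroxide_oracle, db)
        with pytest.warns(UserWarning, match="rejected"):
            add_point(peroxide.coordinates + 1e-9, peroxide_oracle, db)
        assert len(db) == 1

    def test_round_trip(self, peroxide_db, tmp_path):
        path = str(tmp_path / "db.h5")
        save_database(peroxide_db, path)
        back = load_database(path)
        assert len(back) == len(peroxide_db)
        for a, b in zip(peroxide_db.points, back.points):
            assert np.array_equal(a.q, b.q)
            assert a.energy == b.energy
            assert np.array_equal(a.gradient, b.gradient)
            assert np.array_equal(a.hessian, b.hessian)
            assert np.array_equal(a.x_ref, b.x_ref)
            assert a.radius == b.radius
        assert back.weight_mode == peroxide_db.weight_mode

    def test_default_filename(self, peroxide_db, tmp_path, monkeypatch):
        monkeypatch.chdir(tmp_path)
        path = save_database(peroxide_db)
        assert path == "im_database.h5"
        assert (tmp_path / "im_database.h5").exists()

    def test_truncated_file_rejected(self, peroxide_db, tmp_path):
        path = tmp_path / "db.h5"
        save_database(peroxide_db, str(path))
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 3])
        with pytest.raises(IMDatabaseError):
            load_database(str(path))

    def test_foreign_file_rejected(self, tmp_path):
        import h5py

        path = tmp_path / "other.h5"
        with h5py.File(path, "w") as fh:
            fh.create_dataset("something", data=[1, 2, 3])
        with pytest.raises(IMDatabaseError, match="format version"):
            load_database(str(path))


class TestAdaptiveBuild:
    def test_budget_exhausted_returns_unchanged(self, peroxide, peroxide_oracle, peroxide_db):
        settings = IMBuildSettings(max_points=len(peroxide_db))
        db, log = build_database(
            peroxide, peroxide_oracle, PEROXIDE_QUAD, settings, db=peroxide_db
        )
        assert len(db) == len(peroxide_db)
        assert log == []

    def test_frozen_dihedral_relaxation(self, peroxide, peroxide_oracle):
        relaxed = relax_with_frozen_dihedral(peroxide, peroxide_oracle, PEROXIDE_QUAD, 35.0)
        assert geom.dihedral_value(relaxed.coordinates, *PEROXIDE_QUAD) == pytest.approx(
            math.radians(35.0), abs=1e-6
        )
        # perpendicular gradient converged below tolerance
        e, g = peroxide_oracle.energy_gradient(relaxed.coordinates)
        b = np.zeros(12)
        _, dg = geom.dihedral_grad(relaxed.coordinates, *PEROXIDE_QUAD)
        for idx, v in dg.items():
            b[3 * idx : 3 * idx + 3] = v
        gf = g.reshape(-1)
        g_perp = gf - (gf @ b) / (b @ b) * b
        assert np.abs(g_perp).max() < 0.1

    def test_quadratic_oracle_needs_only_seeds(self, peroxide):
        # exactly quadratic in internals (torsion-independent): the seed
        # expansions describe the surface exactly, so sampling never finds an
        # error above threshold
        ics = build_internal_coordinates(peroxide)
        k = np.full(ics.size, 400.0)
        k[ics.periodic_mask] = 0.0
        oracle = QuadraticInternalOracle(ics, peroxide.coordinates, k)
        db, log = build_database(peroxide, oracle, PEROXIDE_QUAD, FAST)
        assert sum(e["points_added"] for e in log) == 0
        x = peroxide.coordinates + np.random.default_rng(0).normal(0, 0.02, (4, 3))
        assert abs(im_energy(x, db) - oracle(x)[0]) < 1e-3

    def test_build_then_validate_under_threshold(self, peroxide, peroxide_oracle):
        db, log = build_database(peroxide, peroxide_oracle, PEROXIDE_QUAD, FAST)
        assert len(db) >= FAST.n_seed_structures
        report, db = confirm_database_quality(peroxide, db, peroxide_oracle, FAST)
        assert report[-1]["additions"] == 0
        assert report[-1]["max_error"] <= FAST.energy_threshold

    def test_self_healing_after_deletion(self, peroxide, peroxide_oracle):
        db, _ = build_database(peroxide, peroxide_oracle, PEROXIDE_QUAD, FAST)
        report, db = confirm_database_quality(peroxide, db, peroxide_oracle, FAST)
        # removing a point re-opens a gap; with a tight threshold the quality
        # loop must detect and repair it, then converge
        tight = IMBuildSettings(
            energy_threshold=0.5,
            n_seed_structures=FAST.n_seed_structures,
            no_add_window_ps=FAST.no_add_window_ps,
            quality_sim_ps=2.0,
            seed=11,
        )
        del db.points[len(db.points) // 2]
        db.invalidate_cache()
        report, healed = confirm_database_quality(peroxide, db, peroxide_oracle, tight)
        assert sum(r["additions"] for r in report) > 0
        assert report[-1]["additions"] == 0
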