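import math

import numpy as np
import pytest

from ffcraft.chem_core import Molecule, perceive_bonds
from ffcraft.data import COULOMB_KE
from ffcraft import geometry as geom
from ffcraft.mm_forcefield import (
    DihedralTerm,
    blank_forcefield,
    evaluate,
    gb_obc2_energy,
    read_gromacs_itp,
    seminario_parameters,
    torsion_energy,
    write_gromacs,
)
from tests.conftest import finite_difference_gradient


class TestTorsionEnergy:
    def test_single_term_at_pi_vanishes(self):
        t = DihedralTerm((0, 1, 2, 3), 1.0, 1, 0.0)
        assert torsion_energy(math.pi, [t]) == pytest.approx(0.0, abs=1e-14)
        assert torsion_energy(0.0, [t]) == pytest.approx(2.0)

    def test_matches_term_by_term_sum(self):
        rng = np.random.default_rng(1)
        terms = [
            DihedralTerm((0, 1, 2, 3), rng.normal(), p, rng.uniform(0, 2 * math.pi))
            for p in (1, 2, 3)
        ]
        for phi in rng.uniform(-math.pi, math.pi, 100):
            ref = sum(t.A * (1 + math.cos(t.p * phi - t.phi0)) for t in terms)
            assert torsion_energy(phi, terms) == pytest.approx(ref, abs=1e-12)

    def test_periodicity(self):
        t = DihedralTerm((0, 1, 2, 3), 2.5, 3, 0.7)
        for phi in np.linspace(-3, 3, 17):
            assert torsion_energy(phi, [t]) == pytest.approx(
                torsion_energy(phi + 2 * math.pi / 3, [t]), abs=1e-10
            )


class TestEvaluate:
    @pytest.fixture
    def distorted_butane(self, butane):
        butane.coordinates += np.random.default_rng(7).normal(0, 0.05, (14, 3))
        return butane

    @pytest.fixture
    def charged_ff(self, butane):
        ff = blank_forcefield(butane)
        ff.charges = np.random.default_rng(2).normal(0, 0.1, 14)
        ff.dihedral_terms += [
            DihedralTerm((0, 1, 2, 3), 5.0, 3, 0.0),
            DihedralTerm((4, 0, 1, 2), 2.0, 1, 0.5),
        ]
        return ff

    def test_equilibrium_bonded_energy_zero(self, water):
        ff = blank_forcefield(water)
        ff.epsilons[:] = 0.0
        comp, _ = evaluate(water, ff)
        assert comp["bond"] == pytest.approx(0.0, abs=1e-12)
        assert comp["angle"] == pytest.approx(0.0, abs=1e-12)
        assert comp["dihedral"] == 0.0

    def test_gradient_matches_finite_differences(self, distorted_butane, charged_ff):
        _, grad = evaluate(distorted_butane, charged_ff)

        def energy_of(x):
            m = distorted_butane.copy()
            m.coordinates = x
            return evaluate(m, charged_ff)[0]["total"]

        fd = finite_difference_gradient(energy_of, distorted_butane.coordinates)
        assert np.abs(fd - grad).max() < 1e-6

    def test_lj_minimum_closed_form(self):
        sigma, eps = 3.4, 0.5
        mol = Molecule(["Ar", "Ar"], [[0, 0, 0], [2 ** (1 / 6) * sigma, 0, 0]])
        ff = blank_forcefield(mol, sigma=sigma, epsilon=eps)
        comp, _ = evaluate(mol, ff)
        assert comp["lj"] == pytest.approx(-eps, rel=1e-12)

    def test_rigid_motion_invariance_and_zero_net_force(self, distorted_butane, charged_ff):
        from scipy.spatial.transform import Rotation

        comp, grad = evaluate(distorted_butane, charged_ff)
        moved = distorted_butane.copy()
        rot = Rotation.from_euler("zyx", [1.1, -0.4, 0.8]).as_matrix()
        moved.coordinates = distorted_butane.coordinates @ rot.T + np.array([1.0, 2.0, 3.0])
        comp2, _ = evaluate(moved, charged_ff)
        assert comp2["total"] == pytest.approx(comp["total"], abs=1e-8)
        assert np.abs(grad.sum(axis=0)).max() < 1e-8  # zero net force
        torque = np.cross(distorted_butane.coordinates, grad).sum(axis=0)
        assert np.abs(torque).max() < 1e-8  # zero net torque

    def test_missing_parameter_names_term(self, water):
        ff = blank_forcefield(water)
        del ff.bond_terms[(0, 1)]
        with pytest.raises(KeyError, match="bond parameter"):
            evaluate(water, ff)


class TestSeminario:
    def test_diatomic_spring_exact(self):
        k = 987.6
        mol = Molecule(["O", "O"], [[0, 0, 0], [0.8, 0.9, -0.3]])
        perceive_bonds(mol)
        u = mol.coordinates[0] - mol.coordinates[1]
        u /= np.linalg.norm(u)
        blk = k * np.outer(u, u)
        hess = np.block([[blk, -blk], [-blk, blk]])
        bonds, _ = seminario_parameters(mol, hess)
        assert bonds[(0, 1)][0] == pytest.approx(k, rel=1e-12)

    def test_zero_hessian_gives_zero_constants(self, water):
        bonds, angles = seminario_parameters(water, np.zeros((9, 9)))
        assert all(k == 0.0 for k, _ in bonds.values())
        assert all(k == 0.0 for k, _ in angles.values())

    def test_angle_constant_from_fd_hessian(self, water):
        k_angle = 345.6
        t0 = geom.angle_value(water.coordinates, 1, 0, 2)

        def pot(flat):
            return 0.5 * k_angle * (geom.angle_value(flat.reshape(-1, 3), 1, 0, 2) - t0) ** 2

        x0 = water.coordinates.reshape(-1)
        h = 1e-4
        hess = np.zeros((9, 9))
        for a in range(9):
            for b in range(9):
                xpp, xpm, xmp, xmm = (x0.copy() for _ in range(4))
                xpp[a] += h; xpp[b] += h
                xpm[a] += h; xpm[b] -= h
                xmp[a] -= h; xmp[b] += h
                xmm[a] -= h; xmm[b] -= h
                hess[a, b] = (pot(xpp) - pot(xpm) - pot(xmp) + pot(xmm)) / (4 * h * h)
        hess = 0.5 * (hess + hess.T)
        _, angles = seminario_parameters(water, hess)
        assert angles[(1, 0, 2)][0] == pytest.approx(k_angle, rel=0.01)

    def test_rotation_invariance(self, water):
        from scipy.spatial.transform import Rotation

        k = 555.0
        u = water.coordinates[0] - water.coordinates[1]
        u /= np.linalg.norm(u)
        mol2 = Molecule(["O", "H"], water.coordinates[:2].copy(), bonds={(0, 1)})
        blk = k * np.outer(u, u)
        hess = np.block([[blk, -blk], [-blk, blk]])
        rot = Rotation.from_euler("xyz", [0.5, 1.0, -0.7]).as_matrix()
        big_rot = np.kron(np.eye(2), rot)
        mol_r = Molecule(["O", "H"], mol2.coordinates @ rot.T, bonds={(0, 1)})
        bonds_r, _ = seminario_parameters(mol_r, big_rot @ hess @ big_rot.T)
        assert bonds_r[(0, 1)][0] == pytest.approx(k, rel=1e-10)

    def test_asymmetric_hessian_rejected(self, water):
        h = np.zeros((9, 9))
        h[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            seminario_parameters(water, h)


class TestGeneralizedBorn:
    def test_zero_charges_zero_energy(self, water):
        assert gb_obc2_energy(water, charges=np.zeros(3)) == 0.0

    def test_born_self_energy_limit(self):
        ion = Molecule(["Na"], [[0.0, 0.0, 0.0]])
        radius, eps = 1.5, 78.5
        e = gb_obc2_energy(ion, charges=[1.0], radii=[radius], dielectric=eps)
        born = -(1 - 1 / eps) * COULOMB_KE / (2 * radius)
        assert e == pytest.approx(born, rel=1e-12)

    def test_distant_pair_approaches_self_terms(self):
        pair = Molecule(["Na", "Na"], [[0, 0, 0], [100.0, 0, 0]])
        radius, eps = 0.5, 78.5
        e = gb_obc2_energy(pair, charges=[1.0, 1.0], radii=[radius, radius], dielectric=eps)
        self_sum = 2 * (-(1 - 1 / eps) * COULOMB_KE / (2 * radius))
        assert e == pytest.approx(self_sum, rel=0.01)

    def test_nonpositive_dielectric_rejected(self, water):
        with pytest.raises(ValueError, match="dielectric"):
            gb_obc2_energy(water, charges=[0.1, 0, 0], dielectric=0.0)


class TestGromacsExport:
    def test_round_trip_and_charge_conservation(self, butane, tmp_path):
        ff = blank_forcefield(butane)
        rng = np.random.default_rng(3)
        ff.charges = rng.normal(0, 0.1, 14)
        ff.charges -= ff.charges.mean()  # neutral molecule
        ff.dihedral_terms += [
            DihedralTerm((0, 1, 2, 3), 4.2, 3, 0.0),
            DihedralTerm((0, 1, 2, 3), 1.1, 1, math.pi),
        ]
        prefix = str(tmp_path / "mol")
        itp, top = write_gromacs(butane, ff, prefix)
        back = read_gromacs_itp(itp)
        assert back.charges.sum() == pytest.approx(butane.formal_charge, abs=1e-6)
        assert np.abs(back.charges - ff.charges).max() < 1e-6
        assert np.abs(back.sigmas - ff.sigmas).max() < 1e-6
        for key, (k, r0) in ff.bond_terms.items():
            k2, r02 = back.bond_terms[key]
            assert k2 == pytest.approx(k, rel=1e-6)
            assert r02 == pytest.approx(r0, abs=1e-6)
        for key, (k, t0) in ff.angle_terms.items():
            k2, t02 = back.angle_terms[key]
            assert k2 == pytest.approx(k, rel=1e-4)
            assert t02 == pytest.approx(t0, abs=1e-5)

    def test_two_terms_two_funct9_lines(self, butane, tmp_path):
        ff = blank_forcefield(butane)
        ff.dihedral_terms += [
            DihedralTerm((0, 1, 2, 3), 4.2, 3, 0.0),
            DihedralTerm((0, 1, 2, 3), 1.1, 1, math.pi),
        ]
        itp, _ = write_gromacs(butane, ff, str(tmp_path / "mol"))
        back = read_gromacs_itp(itp)
        on_quad = [t for t in back.dihedral_terms if t.quad == (0, 1, 2, 3)]
        assert len(on_quad) == 2
        assert sorted((t.p, round(t.A, 6)) for t in on_quad) == [(1, 1.1), (3, 4.2)]
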